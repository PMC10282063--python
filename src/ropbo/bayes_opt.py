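"""Expected-improvement batch Bayesian optimization over a ligand library.

One campaign run mirrors the discovery loop: draw a small random initial
design, fit the GP surrogate on everything observed so far, score the
unobserved candidates with expected improvement (EI), propose a batch of
three, observe their outcomes, and repeat. Two independent campaigns are
run for the two objectives (maximize P_m for isoselective catalysts,
maximize P_r for heteroselective ones). A synthetic-scale budget — summed
expected synthesis steps of the two fragments — can act as a hard
feasibility filter on proposals, so the optimizer never suggests a ligand
that is impractical to make.

Batch selection uses sequential fantasy updates (Kriging believer): after
each pick the surrogate is conditioned on its own predicted mean for that
pick and EI is re-scored, which decorrelates the batch. Plain top-q
ranking is available as a config option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import surrogate
from .catalyst_space import Dataset, synthetic_scale
from .errors import EmptyFeasibleSetError, ValidationError
from .featurization import ligand_feature_frame, preprocess
from .surrogate import GPConfig, GPModel


def expected_improvement(
    mean: np.ndarray | float, std: np.ndarray | float, best: float
) -> np.ndarray | float:
    """Closed-form EI for maximization under a Gaussian posterior.

    EI = (mu - f*) Phi(z) + sigma phi(z) with z = (mu - f*)/sigma; at
    sigma = 0 it degenerates to max(mu - f*, 0). Nonnegative, increasing
    in mu, and increasing in sigma whenever mu <= f*.
    """
    mu = np.asarray(mean, dtype=float)
    sigma = np.asarray(std, dtype=float)
    if np.any(sigma < 0):
        raise ValidationError("std must be >= 0")
    scalar = mu.ndim == 0
    mu, sigma = np.atleast_1d(mu), np.atleast_1d(sigma)
    improvement = mu - best
    ei = np.maximum(improvement, 0.0)
    pos = sigma > 0
    if np.any(pos):
        z = improvement[pos] / sigma[pos]
        ei[pos] = improvement[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    ei = np.maximum(ei, 0.0)
    return float(ei[0]) if scalar else ei


@dataclass
class AcquisitionConfig:
    """Campaign settings: batch size, initial design, budget, cost filter.

    Defaults mirror the retrospective benchmark: 3 random initial points,
    3 proposals per iteration, 12 iterations per run, 10 independent runs,
    and a 3-step synthetic-scale budget (``None`` disables the filter).
    """

    objective: str = "p_m"  # "p_m" or "p_r"
    q: int = 3
    n_init: int = 3
    n_iterations: int = 12
    n_runs: int = 10
    synthetic_scale_max: int | None = 3
    strategy: str = "fantasy"  # or "rank"
    seed: int = 0
    gp: GPConfig = field(default_factory=lambda: GPConfig(n_restarts=2))
    corr_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.q < 1 or self.n_init < 1 or self.n_iterations < 1 or self.n_runs < 1:
            raise ValidationError("q, n_init, n_iterations, n_runs must be >= 1")
        if self.objective not in ("p_m", "p_r"):
            raise ValidationError(f"objective must be 'p_m' or 'p_r', got {self.objective!r}")
        if self.strategy not in ("fantasy", "rank"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")


@dataclass
class CandidatePool:
    """A finite ligand design space with features, outcomes, and costs.

    ``features`` is a raw (unpreprocessed) matrix indexed by ligand id;
    ``objective`` maps ligand id to the observable outcome (table lookup
    for retrospective data, generator call for synthetic landscapes);
    ``scales`` maps ligand id to synthetic-scale step counts.
    """

    features: pd.DataFrame
    objective: Mapping[str, float] | Callable[[str], float]
    scales: Mapping[str, int] | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.features.index)

    def observe(self, ligand_id: str) -> float:
        if callable(self.objective):
            return float(self.objective(ligand_id))
        return float(self.objective[ligand_id])

    def scale_of(self, ligand_id: str) -> int | None:
        if self.scales is None:
            return None
        return self.scales.get(ligand_id)

    @classmethod
    def from_dataset(
        cls,
        dataset: Dataset,
        a_table: pd.DataFrame,
        bc_table: pd.DataFrame,
        objective: str = "p_m",
    ) -> "CandidatePool":
        """Retrospective pool: outcomes are looked up from a dataset."""
        ligands = [r.ligand for r in dataset.records]
        features = ligand_feature_frame(ligands, a_table, bc_table)
        values = dataset.outcome(objective)
        lookup = {lg.id: float(v) for lg, v in zip(ligands, values)}
        scales = None
        if dataset.fragment_registry:
            scales = {
                lg.id: synthetic_scale(lg, dataset.fragment_registry)
                for lg in ligands
            }
        return cls(features=features, objective=lookup, scales=scales)


@dataclass
class ProposalBatch:
    """An ordered batch of proposed ligands with their acquisition scores."""

    ids: list[str]
    ei: list[float]
    truncated: bool = False  # fewer feasible candidates than requested


def propose_batch(
    model: GPModel,
    candidates: pd.DataFrame,
    q: int,
    best: float,
    scales: Mapping[str, int] | None = None,
    max_scale: int | None = None,
    strategy: str = "fantasy",
) -> ProposalBatch:
    """Select q distinct ligands by constraint-filtered EI.

    ``candidates`` must already carry the training preprocessing transform
    and exclude observed ligands. Ligands over the synthetic-scale budget
    are removed before scoring. With ``strategy="fantasy"`` each pick
    conditions the surrogate on its own predicted mean before re-scoring
    (so the first pick always equals the q=1 answer); ``"rank"`` takes the
    plain top q by EI.
    """
    pool = candidates
    if max_scale is not None and scales is not None:
        feasible = [i for i in pool.index if scales.get(i, max_scale + 1) <= max_scale]
        pool = pool.loc[feasible]
    if len(pool) == 0:
        raise EmptyFeasibleSetError(
            "no candidate satisfies the synthetic-scale budget"
        )
    truncated = len(pool) < q
    q_eff = min(q, len(pool))

    if strategy == "rank":
        mean, std = surrogate.predict_arrays(model, pool.to_numpy(dtype=float))
        ei = expected_improvement(mean, std, best)
        order = np.argsort(-ei, kind="stable")[:q_eff]
        return ProposalBatch(
            ids=[pool.index[i] for i in order],
            ei=[float(ei[i]) for i in order],
            truncated=truncated,
        )

    # sequential fantasy (Kriging believer)
    picked_ids: list[str] = []
    picked_ei: list[float] = []
    fantasy = model
    X_fant = model.X_train
    y_fant = model.y_train
    remaining = pool.copy()
    for _ in range(q_eff):
        mean, std = surrogate.predict_arrays(
            fantasy, remaining.to_numpy(dtype=float)
        )
        ei = expected_improvement(mean, std, best)
        i = int(np.argmax(ei))
        lig = remaining.index[i]
        picked_ids.append(lig)
        picked_ei.append(float(ei[i]))
        if len(picked_ids) < q_eff:
            x_new = remaining.to_numpy(dtype=float)[i : i + 1]
            X_fant = np.vstack([X_fant, x_new])
            y_fant = np.append(y_fant, mean[i])
            fantasy = surrogate.refit_fixed(fantasy, X_fant, y_fant)
        remaining = remaining.drop(index=lig)
    return ProposalBatch(ids=picked_ids, ei=picked_ei, truncated=truncated)


@dataclass
class CampaignTrace:
    """Per-run, per-iteration record of a repeated optimization campaign.

    ``best_so_far`` has shape (n_runs, n_iterations + 1); column 0 is the
    best of the random initial design, column t the best after iteration t.
    """

    objective: str
    method: str
    init_ids: list[list[str]]
    proposals: list[list[list[str]]]
    ei_scores: list[list[list[float]]]
    observations: list[list[list[float]]]
    best_so_far: np.ndarray
    run_seeds: list[int]

    @property
    def n_runs(self) -> int:
        return self.best_so_far.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.best_so_far.shape[1] - 1

    def best_mean(self) -> np.ndarray:
        return self.best_so_far.mean(axis=0)

    def best_sd(self) -> np.ndarray:
        return self.best_so_far.std(axis=0, ddof=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_runs):
            for t in range(self.n_iterations):
                for lig, ei, obs in zip(
                    self.proposals[r][t],
                    self.ei_scores[r][t],
                    self.observations[r][t],
                ):
                    rows.append(
                        {
                            "run": r,
                            "iteration": t + 1,
                            "ligand": lig,
                            "ei": ei,
                            "observed": obs,
                            "best_so_far": self.best_so_far[r, t + 1],
                        }
                    )
        return pd.DataFrame(rows)


def _campaign_loop(
    pool: CandidatePool,
    config: AcquisitionConfig,
    method: str,
) -> CampaignTrace:
    ids = pool.ids
    if len(ids) < config.n_init:
        raise ValidationError(
            f"space of {len(ids)} candidates is smaller than n_init={config.n_init}"
        )
    # Preprocessing statistics come from the full candidate library:
    # descriptors are known for the whole design space before any outcome
    # is observed, so this uses no outcome information.
    fm = preprocess(pool.features, corr_threshold=config.corr_threshold)
    X_all = fm.frame

    master = np.random.default_rng(config.seed)
    run_seeds = [int(master.integers(2**31)) for _ in range(config.n_runs)]

    init_ids, proposals, ei_scores, observations = [], [], [], []
    best = np.zeros((config.n_runs, config.n_iterations + 1))

    for r, rs in enumerate(run_seeds):
        rng = np.random.default_rng(rs)
        observed = list(rng.choice(ids, size=config.n_init, replace=False))
        values = {lig: pool.observe(lig) for lig in observed}
        init_ids.append(list(observed))
        best[r, 0] = max(values.values())
        run_props, run_eis, run_obs = [], [], []

        for t in range(1, config.n_iterations + 1):
            unobserved = [i for i in ids if i not in values]
            batch_ids: list[str] = []
            batch_ei: list[float] = []
            if unobserved:
                if method == "bo":
                    gp_cfg = GPConfig(
                        kernel=config.gp.kernel,
                        ard=config.gp.ard,
                        noise=config.gp.noise,
                        n_restarts=config.gp.n_restarts,
                        seed=int(rng.integers(2**31)),
                    )
                    model = surrogate.fit(
                        X_all.loc[observed],
                        [values[i] for i in observed],
                        gp_cfg,
                    )
                    try:
                        batch = propose_batch(
                            model,
                            X_all.loc[unobserved],
                            config.q,
                            best=max(values.values()),
                            scales=pool.scales,
                            max_scale=config.synthetic_scale_max,
                            strategy=config.strategy,
                        )
                        batch_ids, batch_ei = batch.ids, batch.ei
                    except EmptyFeasibleSetError:
                        batch_ids, batch_ei = [], []
                else:  # uniform random proposals under the same constraint
                    feasible = unobserved
                    if (
                        config.synthetic_scale_max is not None
                        and pool.scales is not None
                    ):
                        feasible = [
                            i
                            for i in unobserved
                            if pool.scales.get(
                                i, config.synthetic_scale_max + 1
                            )
                            <= config.synthetic_scale_max
                        ]
                    if feasible:
                        k = min(config.q, len(feasible))
                        batch_ids = list(
                            rng.choice(feasible, size=k, replace=False)
                        )
                        batch_ei = [float("nan")] * k
            obs = []
            for lig in batch_ids:
                y = pool.observe(lig)
                values[lig] = y
                observed.append(lig)
                obs.append(y)
            run_props.append(batch_ids)
            run_eis.append(batch_ei)
            run_obs.append(obs)
            best[r, t] = max(values.values())
        proposals.append(run_props)
        ei_scores.append(run_eis)
        observations.append(run_obs)

    return CampaignTrace(
        objective=config.objective,
        method=method,
        init_ids=init_ids,
        proposals=proposals,
        ei_scores=ei_scores,
        observations=observations,
        best_so_far=best,
        run_seeds=run_seeds,
    )


def run_campaign(
    pool: CandidatePool, config: AcquisitionConfig
) -> CampaignTrace:
    """Repeated EI-guided campaigns (fit -> propose q -> observe -> refit)."""
    return _campaign_loop(pool, config, method="bo")


def random_baseline(
    pool: CandidatePool, config: AcquisitionConfig
) -> CampaignTrace:
    """Random-search baseline: uniform proposals without replacement."""
    return _campaign_loop(pool, config, method="random")


def convergence_iteration(
    trace: CampaignTrace, global_max: float, tol: float = 1e-9
) -> int | None:
    """First iteration at which every run has found the global optimum.

    Equivalently, the first iteration where the cross-run standard
    deviation of best-so-far collapses to zero at the optimum. Returns
    ``None`` if some run never reaches it. Iteration 0 is the initial
    random design.
    """
    if trace.n_runs < 2:
        raise ValidationError("need at least 2 runs to assess convergence")
    hit = np.all(trace.best_so_far >= global_max - tol, axis=0)
    idx = np.flatnonzero(hit)
    return int(idx[0]) if idx.size else None
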