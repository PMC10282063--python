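"""Bundled fixture data.

Every file here is a *synthetic stand-in*, re-keyed to anonymous fragment
ids, constructed so that its summary statistics match the published facts
about the 56-complex literature dataset for Al-catalyzed rac-lactide ROP
(record count, the number of hetero-leaning records, the extreme P_m
values, the step counts of the anchor ligands). The per-fragment
descriptor tables are synthetic DFT-style aggregates, not quantum-chemistry
output. ``table1_complexes.csv`` transcribes the printed outcomes of the
eight representative complexes (measured P_m, conversion, M_n, dispersity)
under the re-keyed fragment ids.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..bayes_opt import CandidatePool
from ..catalyst_space import Dataset, load_dataset, load_fragment_registry

_PKG = "ropbo.data"


def _path(name: str):
    return resources.files(_PKG).joinpath(name)


def load_registry() -> dict:
    """Fragment registry for the full 16-arene x 36-linker design space."""
    with resources.as_file(_path("fragment_registry_synthetic.csv")) as p:
        return load_fragment_registry(p)


def load_literature_dataset() -> Dataset:
    """The 56-record re-keyed literature stand-in, with registry attached."""
    registry = load_registry()
    with resources.as_file(_path("literature_rekeyed_synthetic.csv")) as p:
        return load_dataset(p, fragment_registry=registry)


def load_table1() -> Dataset:
    """The eight representative complexes with printed outcomes."""
    with resources.as_file(_path("table1_complexes.csv")) as p:
        return load_dataset(p)


def load_fragment_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(arene, linker) descriptor tables indexed by fragment id."""
    with resources.as_file(_path("arene_descriptors_synthetic.csv")) as p:
        a = pd.read_csv(p).set_index("fragment_id")
    with resources.as_file(_path("linker_descriptors_synthetic.csv")) as p:
        bc = pd.read_csv(p).set_index("fragment_id")
    return a, bc


def literature_pool(objective: str = "p_m") -> CandidatePool:
    """Retrospective candidate pool over the 56-record stand-in."""
    dataset = load_literature_dataset()
    a, bc = load_fragment_tables()
    return CandidatePool.from_dataset(dataset, a, bc, objective=objective)
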