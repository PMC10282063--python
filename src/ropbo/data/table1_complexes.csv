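a_id,bc_id,temp_C,conc_M,ratio,p_m,conversion,m_n_kDa,dispersity,source
A11,C3B1,70.0,1.39,100.0,0.95,0.952,14.0,1.03,round-1
A11,C2B1,70.0,1.39,100.0,0.92,0.97,32.2,1.05,round-1
A5,C1B2,70.0,1.39,100.0,0.06,0.781,11.1,1.01,round-2
A5,C1B3,70.0,1.39,100.0,0.07,0.813,8.3,1.06,round-2
A16,C1B2,70.0,1.39,100.0,0.07,0.877,12.9,1.04,round-2
A16,C1B3,70.0,1.39,100.0,0.07,0.588,15.9,1.08,round-2
A3,C3B1,70.0,1.39,100.0,0.94,0.962,11.9,1.16,literature
A6,C1B3,70.0,1.39,100.0,0.11,0.758,12.5,1.09,literature
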