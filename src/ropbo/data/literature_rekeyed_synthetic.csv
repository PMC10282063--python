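a_id,bc_id,temp_C,conc_M,ratio,p_m,conversion,m_n_kDa,dispersity,source
A6,C1B3,70.0,1.39,100.0,0.11,0.783,22.8,1.1,literature
A6,C1B2,70.0,1.39,100.0,0.14,0.729,13.7,1.15,literature
A7,C1B3,70.0,1.39,100.0,0.13,0.855,11.3,1.18,literature
A6,C1B1,70.0,1.39,100.0,0.25,0.903,8.0,1.02,literature
A7,C1B1,70.0,1.39,100.0,0.29,0.577,19.9,1.05,literature
A16,C1B2,70.0,1.39,100.0,0.2,0.722,12.0,1.21,literature
A16,C1B1,70.0,1.39,100.0,0.33,0.901,7.4,1.16,literature
A13,C1B3,70.0,1.39,100.0,0.27,0.647,12.9,1.02,literature
A8,C1B3,70.0,1.39,100.0,0.29,0.588,20.5,1.04,literature
A3,C3B1,70.0,1.39,100.0,0.94,0.607,32.0,1.07,literature
A15,C3B1,70.0,1.39,100.0,0.93,0.786,25.7,1.17,literature
A11,C3B1,70.0,1.39,100.0,0.93,0.646,22.6,1.16,literature
A14,C3B1,70.0,1.39,100.0,0.92,0.623,16.5,1.17,literature
A10,C3B1,70.0,1.39,100.0,0.92,0.809,28.3,1.14,literature
A5,C2B2,70.0,1.39,100.0,0.76,0.682,25.8,1.21,literature
A1,C2B1,70.0,1.39,100.0,0.83,0.697,16.8,1.12,literature
A1,C2B2,70.0,1.39,100.0,0.78,0.757,15.1,1.2,literature
A1,C3B2,70.0,1.39,100.0,0.82,0.841,27.9,1.18,literature
A1,C3B3,70.0,1.39,100.0,0.75,0.878,17.6,1.1,literature
A2,C2B1,70.0,1.39,100.0,0.87,0.824,12.8,1.12,literature
A2,C2B2,70.0,1.39,100.0,0.82,0.959,25.3,1.04,literature
A2,C3B2,70.0,1.39,100.0,0.86,0.639,26.4,1.05,literature
A2,C2B4,70.0,1.39,100.0,0.85,0.842,9.6,1.21,literature
A3,C2B1,70.0,1.39,100.0,0.91,0.663,9.6,1.12,literature
A3,C2B2,70.0,1.39,100.0,0.88,0.932,34.5,1.21,literature
A3,C3B2,70.0,1.39,100.0,0.9,0.611,13.7,1.1,literature
A3,C1B1,70.0,1.39,100.0,0.76,0.672,18.1,1.13,literature
A4,C2B1,70.0,1.39,100.0,0.86,0.777,16.5,1.16,literature
A4,C3B2,70.0,1.39,100.0,0.85,0.729,28.1,1.2,literature
A4,C3B3,70.0,1.39,100.0,0.79,0.915,31.4,1.25,literature
A4,C2B3,70.0,1.39,100.0,0.75,0.879,15.2,1.08,literature
A8,C2B1,70.0,1.39,100.0,0.79,0.872,11.3,1.13,literature
A8,C3B1,70.0,1.39,100.0,0.85,0.581,17.3,1.07,literature
A8,C3B2,70.0,1.39,100.0,0.77,0.975,14.5,1.12,literature
A8,C2B2,70.0,1.39,100.0,0.72,0.581,23.4,1.01,literature
A9,C2B1,70.0,1.39,100.0,0.85,0.651,18.1,1.1,literature
A9,C3B2,70.0,1.39,100.0,0.83,0.796,19.7,1.16,literature
A9,C3B3,70.0,1.39,100.0,0.77,0.714,26.4,1.19,literature
A9,C2B4,70.0,1.39,100.0,0.82,0.594,27.0,1.08,literature
A10,C2B1,70.0,1.39,100.0,0.88,0.585,24.3,1.07,literature
A10,C2B2,70.0,1.39,100.0,0.84,0.97,20.9,1.12,literature
A10,C3B2,70.0,1.39,100.0,0.87,0.818,33.1,1.18,literature
A11,C2B1,70.0,1.39,100.0,0.9,0.828,23.2,1.07,literature
A11,C2B2,70.0,1.39,100.0,0.86,0.692,9.6,1.23,literature
A11,C3B2,70.0,1.39,100.0,0.89,0.583,10.5,1.2,literature
A12,C2B1,70.0,1.39,100.0,0.8,0.791,30.4,1.1,literature
A12,C3B2,70.0,1.39,100.0,0.79,0.784,11.2,1.13,literature
A12,C2B4,70.0,1.39,100.0,0.77,0.96,8.2,1.21,literature
A13,C2B1,70.0,1.39,100.0,0.77,0.879,17.6,1.07,literature
A13,C3B2,70.0,1.39,100.0,0.75,0.757,16.9,1.21,literature
A13,C3B1,70.0,1.39,100.0,0.83,0.953,31.7,1.17,literature
A14,C2B1,70.0,1.39,100.0,0.89,0.793,11.2,1.05,literature
A14,C3B2,70.0,1.39,100.0,0.88,0.987,13.1,1.2,literature
A1,C2B3,70.0,1.39,100.0,0.71,0.951,23.7,1.12,literature
A2,C3B3,70.0,1.39,100.0,0.8,0.703,16.8,1.08,literature
A12,C3B3,70.0,1.39,100.0,0.71,0.742,30.6,1.14,literature
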