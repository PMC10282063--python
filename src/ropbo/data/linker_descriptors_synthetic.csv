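fragment_id,vbur_min,e_homo,en,freq_min,mulliken_mean,dipole
C1B1,25.0846,-6.0636,4.552,67.9355,-0.1297,2.3871
C2B1,19.8595,-6.4811,4.9965,88.1614,-0.0449,1.3989
C3B1,18.0483,-6.6811,5.0729,86.0725,-0.0061,1.9555
C1B2,27.6735,-5.7195,4.1781,80.698,0.0951,0.3573
C2B2,21.108,-6.3725,4.8261,64.582,0.0315,0.7446
C3B2,20.4052,-6.4744,4.8945,101.0723,0.042,1.9501
C1B3,29.0455,-5.6578,4.1211,75.8102,-0.077,1.4133
C2B3,22.8059,-6.1663,4.5887,81.5647,0.0142,2.332
C3B3,21.8201,-6.3915,4.8,84.4281,-0.0521,1.157
C1B4,25.5152,-5.9796,4.4277,93.371,-0.1206,2.2631
C2B4,20.7354,-6.4671,4.9092,87.8988,-0.0987,1.8498
C3B4,21.1512,-6.3186,4.7055,87.2119,0.087,2.1211
C1B5,25.5424,-5.854,4.2531,81.8155,0.2848,1.6135
C2B5,20.927,-6.4025,4.8473,81.2016,-0.0035,3.0189
C3B5,24.2613,-6.0784,4.4976,87.5621,-0.0481,1.1664
C1B6,20.4661,-6.3694,4.829,85.6854,0.1666,1.9847
C2B6,19.3,-6.5628,4.9965,64.1441,0.1071,0.1528
C3B6,21.3995,-6.3761,4.8689,84.2767,0.0926,2.7538
C1B7,26.2184,-5.8568,4.368,104.8287,-0.0692,1.0754
C2B7,20.3218,-6.3785,4.7804,94.5402,0.0068,1.4143
C3B7,23.98,-6.0795,4.4891,102.8953,-0.0234,0.8313
C1B8,21.246,-6.3785,4.738,87.8159,0.097,2.7687
C2B8,26.6695,-5.8745,4.3342,107.7113,0.0877,1.1737
C3B8,26.1453,-5.9483,4.38,93.7413,0.0983,1.3044
C1B9,22.1359,-6.3196,4.7283,91.0429,0.1003,2.1671
C2B9,22.4229,-6.3174,4.7245,106.0556,-0.0848,1.5514
C3B9,27.3584,-5.8653,4.4218,81.2413,0.0164,1.6637
C1B10,21.1534,-6.4156,4.8914,68.0317,-0.1235,2.4697
C2B10,19.887,-6.4854,4.8974,61.4063,0.0018,2.4771
C3B10,24.1343,-6.0616,4.5709,104.4539,0.1748,1.8267
C1B11,23.9484,-6.1326,4.6368,64.3241,-0.01,1.1915
C2B11,22.9407,-6.2775,4.7422,72.8034,-0.1229,1.6091
C3B11,25.3848,-5.9174,4.354,67.8054,-0.0382,1.913
C1B12,24.3916,-6.0795,4.5081,97.8965,0.0609,2.291
C2B12,21.6481,-6.3698,4.8353,67.9466,-0.1,1.4416
C3B12,26.3218,-5.9125,4.3652,95.1337,0.0321,2.1488
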