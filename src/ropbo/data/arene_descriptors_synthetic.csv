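fragment_id,vbur_max,e_homo,en,freq_min,mulliken_mean,dipole
A1,60.9983,-6.1193,4.4059,144.6193,-0.1061,2.9754
A2,62.1604,-6.2012,4.5598,132.3084,-0.0574,3.0299
A3,64.6134,-6.3717,4.6989,153.5407,0.0722,1.6376
A4,62.0379,-6.166,4.4875,130.0184,-0.022,2.4585
A5,60.3424,-6.0023,4.2631,148.8207,0.1578,2.0698
A6,53.3557,-5.3938,3.6718,154.6577,-0.0714,3.3748
A7,54.5163,-5.4331,3.7883,114.3263,-0.1225,2.2019
A8,59.8676,-5.874,4.1781,128.43,0.0109,2.2567
A9,61.6433,-6.1116,4.3619,144.9339,-0.1081,1.8123
A10,62.6187,-6.2508,4.5784,138.3537,0.0649,2.3795
A11,64.1236,-6.3634,4.6414,148.4014,-0.0342,3.0042
A12,60.2531,-5.9459,4.1742,133.7458,-0.0359,1.9602
A13,59.0523,-5.9138,4.2105,129.8214,0.1078,2.1874
A14,63.3306,-6.2794,4.6382,147.0127,0.0101,1.8233
A15,63.7813,-6.3935,4.6949,133.4646,0.0363,3.0628
A16,54.9852,-5.6221,3.9439,116.7342,-0.0169,2.3495
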