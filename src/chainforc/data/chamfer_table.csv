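aspect,chamfer,axial_ratio
1.000,0.000,1.000000
1.000,0.050,1.002169
1.000,0.100,1.001468
1.000,0.150,0.999492
1.000,0.200,0.997239
1.000,0.250,0.995402
1.000,0.300,0.991555
1.000,0.350,0.988050
1.000,0.400,0.983861
1.000,0.450,0.976054
1.250,0.000,1.000000
1.250,0.050,1.000878
1.250,0.100,0.997314
1.250,0.150,0.991486
1.250,0.200,0.984809
1.250,0.250,0.978295
1.250,0.300,0.969630
1.250,0.350,0.961541
1.250,0.400,0.953173
1.250,0.450,0.941759
1.500,0.000,1.000000
1.500,0.050,0.999611
1.500,0.100,0.993242
1.500,0.150,0.983692
1.500,0.200,0.972816
1.500,0.250,0.961952
1.500,0.300,0.948971
1.500,0.350,0.936886
1.500,0.400,0.924987
1.500,0.450,0.910634
1.750,0.000,1.000000
1.750,0.050,0.998355
1.750,0.100,0.989240
1.750,0.150,0.976109
1.750,0.200,0.961270
1.750,0.250,0.946385
1.750,0.300,0.929541
1.750,0.350,0.913979
1.750,0.400,0.899106
1.750,0.450,0.882377
2.000,0.000,1.000000
2.000,0.050,0.997111
2.000,0.100,0.985313
2.000,0.150,0.968752
2.000,0.200,0.950192
2.000,0.250,0.931609
2.000,0.300,0.911310
2.000,0.350,0.892716
2.000,0.400,0.875328
2.000,0.450,0.856669
2.250,0.000,1.000000
2.250,0.050,0.995879
2.250,0.100,0.981472
2.250,0.150,0.961637
2.250,0.200,0.939595
2.250,0.250,0.917621
2.250,0.300,0.894233
2.250,0.350,0.872986
2.250,0.400,0.853455
2.250,0.450,0.833218
2.500,0.000,1.000000
2.500,0.050,0.994662
2.500,0.100,0.977722
2.500,0.150,0.954771
2.500,0.200,0.929481
2.500,0.250,0.904404
2.500,0.300,0.878249
2.500,0.350,0.854671
2.500,0.400,0.833302
2.500,0.450,0.811758
2.750,0.000,1.000000
2.750,0.050,0.993461
2.750,0.100,0.974066
2.750,0.150,0.948157
2.750,0.200,0.919842
2.750,0.250,0.891927
2.750,0.300,0.863290
2.750,0.350,0.837654
2.750,0.400,0.814694
2.750,0.450,0.792057
3.000,0.000,1.000000
3.000,0.050,0.992276
3.000,0.100,0.970507
3.000,0.150,0.941792
3.000,0.200,0.910662
3.000,0.250,0.880152
3.000,0.300,0.849285
3.000,0.350,0.821823
3.000,0.400,0.797473
3.000,0.450,0.773913
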