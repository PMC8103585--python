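eccentricity_mm,density_cells_per_mm2
0,223194.27202033115
0.10000000000000001,215576.51885460661
0.20000000000000001,190392.46882447955
0.30000000000000004,155877.66946125287
0.40000000000000002,121354.03936979668
0.5,93625.516156556216
0.60000000000000009,75440.616535031295
0.70000000000000007,66149.01303640315
0.80000000000000004,63414.684038795203
0.90000000000000002,64749.308015277435
1,68295.194318994923
1.1000000000000001,72945.432066113543
1.2000000000000002,78145.715892025793
1.3,83653.450167235482
1.4000000000000001,89369.401617275827
1.5,95249.07063190185
1.6000000000000001,101264.80406024965
1.7000000000000002,107392.22850343856
1.8,113606.15111563263
1.9000000000000001,119879.5668195232
2,126183.55419007348
2.1000000000000001,132487.41050463423
2.2000000000000002,138758.86268890239
2.3000000000000003,144964.31748401347
2.4000000000000004,151069.14196462414
2.5,157037.97040472241
2.6000000000000001,162835.03381140606
2.7000000000000002,168424.50802662215
2.8000000000000003,173770.87581774712
2.9000000000000004,178839.29795658967
3,183595.98794918149
3.1000000000000001,188008.58483794244
3.2000000000000002,192046.51836230891
3.3000000000000003,195681.36073999418
3.4000000000000004,198887.15942235588
3.5,201640.74538472071
3.6000000000000001,203922.0118338941
3.7000000000000002,205714.15864548596
3.8000000000000003,207003.89837530712
3.9000000000000004,207781.62031145216
4,208041.50973389071
4.1000000000000005,205742.73204062655
4.2000000000000002,203469.35494597277
4.2999999999999998,201221.09778320303
4.4000000000000004,198997.68298684907
4.5,196798.83605843291
4.6000000000000005,194624.28553257804
4.7000000000000002,192473.76294349454
4.8000000000000007,190347.00279183508
4.9000000000000004,188243.74251191661
5,186163.72243930481
5.1000000000000005,184106.68577875619
5.2000000000000002,182072.3785725148
5.3000000000000007,180060.54966895891
5.4000000000000004,178070.95069159454
5.5,176103.33600839131
5.6000000000000005,174157.46270145697
5.7000000000000002,172233.09053704762
5.8000000000000007,170329.98193590861
5.9000000000000004,168447.90194394361
6,166586.6182032075
6.1000000000000005,164745.90092322003
6.2000000000000002,162925.52285259642
6.3000000000000007,161125.25925099108
6.4000000000000004,159344.8878613518
6.5,157584.18888248026
6.6000000000000005,155842.94494189584
6.7000000000000002,154120.94106899921
6.8000000000000007,152417.96466853243
6.9000000000000004,150733.80549433245
7,149068.25562337443
7.1000000000000005,147421.10943010208
7.2000000000000002,145792.16356104138
7.3000000000000007,144181.21690969507
7.4000000000000004,142588.07059171441
7.5,141012.52792034525
7.6000000000000005,139454.39438214549
7.7000000000000002,137913.47761297098
7.8000000000000007,136389.58737422631
7.9000000000000004,134882.53552937854
8,133392.13602073025
8.0999999999999996,131918.20484644899
8.2000000000000011,130460.5600378511
8.3000000000000007,129019.02163693597
8.4000000000000004,127593.41167416883
8.5,126183.55414650898
8.5999999999999996,124789.2749956808
8.7000000000000011,123410.4020866848
8.8000000000000007,122046.76518654646
8.9000000000000004,120698.19594329904
9,119364.52786519971
9.0999999999999996,118045.59630017451
9.2000000000000011,116741.23841549075
9.3000000000000007,115451.29317765418
9.4000000000000004,114175.60133252788
9.5,112914.00538567113
9.6000000000000014,111666.34958289551
9.7000000000000011,110432.47989103572
9.8000000000000007,109212.24397893304
9.9000000000000004,108005.49119862866
10,106812.07256676511
10.100000000000001,105631.84074619303
10.200000000000001,104464.65002778122
10.300000000000001,103310.35631242758
10.4,102168.8170932691
10.5,101039.89143808803
10.600000000000001,99923.439971912783
10.700000000000001,98819.324859811022
10.800000000000001,97727.409789872705
10.9,96647.559956381301
11,95579.642043170985
11.100000000000001,94523.524207167677
11.200000000000001,93479.07606211197
11.300000000000001,92446.168662461801
11.4,91424.674487473225
11.5,90414.467425456765
11.600000000000001,89415.422758208122
11.700000000000001,88427.417145610583
11.800000000000001,87450.32861040764
11.9,86484.036523144081
12,85528.421587273144
12.100000000000001,84583.36582442846
12.200000000000001,83648.752559858782
12.300000000000001,82724.466408023334
12.4,81810.393258346681
12.5,80906.420261130828
12.600000000000001,80012.435813623015
12.700000000000001,79128.329546237452
12.800000000000001,78253.992308929315
12.9,77389.316157719251
13,76534.194341366892
13.100000000000001,75688.521288191478
13.200000000000001,74852.1925930383
13.300000000000001,74025.105004388868
13.4,73207.156411613876
13.5,72398.245832366607
13.600000000000001,71598.273400116028
13.700000000000001,70807.140351817434
13.800000000000001,70024.749015719251
13.9,69251.00279930477
14,68485.806177366947
14.100000000000001,67729.064680215146
14.200000000000001,66980.684882012021
14.300000000000001,66240.574389239322
14.4,65508.641829291257
14.5,64784.796839193717
14.600000000000001,64068.950054448287
14.700000000000001,63361.013097999501
14.800000000000001,62660.898569323923
14.9,61968.52003363987
15,61283.792011236379
15.100000000000001,60606.629966919987
15.200000000000001,59936.950299578231
15.300000000000001,59274.670331858368
15.4,58619.708299960243
15.5,57971.983343541855
15.600000000000001,57331.415495736488
15.700000000000001,56697.925673280217
15.800000000000001,56071.435666748352
15.9,55451.8681308999
16,54839.146575128703
16.100000000000001,54233.195354019997
16.199999999999999,53633.939658011426
16.300000000000001,53041.305504157135
16.400000000000002,52455.219726994052
16.5,51875.609969509016
16.600000000000001,51302.404674205609
16.699999999999999,50735.533074269995
16.800000000000001,50174.925184833977
16.900000000000002,49620.511794334976
17,49072.224455971256
17.100000000000001,48529.995479251505
17.199999999999999,47993.757921638076
17.300000000000001,47463.445580282234
17.400000000000002,46938.992983851014
17.5,46420.335384444159
17.600000000000001,45907.408749600479
17.699999999999999,45400.149754392623
17.800000000000001,44898.495773608949
17.900000000000002,44402.384874022093
18,43911.755806742724
18.100000000000001,43426.547999657865
18.199999999999999,42946.701549952864
18.300000000000001,42472.157216715772
18.400000000000002,42002.856413623733
18.5,41538.74120170992
18.600000000000001,41079.75428221051
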