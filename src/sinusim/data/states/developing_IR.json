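{"y": [12411.443958479245, 3824.408785681658, 393.9701055872834, 1384.1358339027638, 149.89217715982608, 0.22659648306682542, 0.013402948695251575, 65.0, 12419.747423847788, 3748.9230976963386, 388.18977063978775, 1385.4620661109627, 149.0869621263908, 0.2103081860779896, 0.012970426907268295, 61.25, 12482.3365204645, 253.1962107553385, 307352.24130537227, 1038.8935153022655, 3344.7980734828307, 105.04194805376254, 7.139275059697965, 26878.213984054506, 87.47786490171386, 2914.6031443829484, 722.50783550446, 162.8890201124351, 4059.193425622433, 387.09478840456643, 12.90521159543021, 352.58880704845757, 47.41119295151804, 12420.499948142673, 3689.1620909871617, 382.85240526065985, 1386.8167189780709, 148.28484341013967, 0.19519071826179074, 0.012551863546056115, 57.5, 12399.524210260326, 288.6668234097374, 309216.62413629337, 1121.9867679343783, 3368.8851990596736, 109.35756768520368, 7.9066326603571175, 27137.97382726193, 87.21511371261303, 2848.0955003145727, 767.5917053742221, 184.3127943109825, 4101.700793338868, 388.0278784107996, 11.972121589126912, 357.93723312940296, 42.06276687060054, 12413.465456329805, 3645.436253782211, 377.9576385960361, 1388.2152929928943, 147.48654411844387, 0.18115991942840465, 0.012146808121113158, 53.75, 12306.856244933437, 325.2546935725534, 309249.69386805926, 1198.7953687889467, 3410.6610509101183, 114.50649435267722, 8.933227797784136, 27535.85823895482, 86.99725490546868, 2764.3611576532953, 822.2312617678659, 213.40758057922307, 4145.578112272555, 388.85832814274295, 11.141671857238164, 362.84152373111687, 37.158476268921454, 12398.395401170368, 3618.074870898132, 373.504658146434, 1389.6773033197887, 146.69315510346965, 0.1681376788279325, 0.011754824681633637, 50.0, 12204.131250410479, 361.5520479360801, 307190.13151755126, 1273.1294114009286, 3470.5550767050336, 120.51668669357008, 10.290363559596782, 28109.07560528098, 86.84745354117457, 2653.255062841045, 890.9356531304322, 255.80928402848994, 4193.975778060015, 389.5802740767921, 10.419725923195484, 367.36199777191683, 32.63800222814335, 12374.976029545847, 3607.633099347862, 369.48946139327353, 1391.2271152453955, 145.9063721136699, 0.1560515003210103, 0.011375491347212942, 46.25, 12090.530467598197, 393.6893980854808, 302476.89117694227, 1350.9766602255534, 3550.326563662706, 127.53570288393047, 12.04852231143171, 28903.793069352396, 86.80393369945152, 2500.016164089699, 977.9311496618534, 322.0526862483212, 4251.354330456918, 390.18351600554547, 9.816483994473616, 371.54545480390186, 28.454545196126652, 12342.85775204717, 3615.050218076761, 365.9013063823974, 1392.8935174651313, 145.12901170665717, 0.14483409880429352, 0.011008399853701426, 42.5, 11965.553925071217, 414.44032650870525, 294197.09447763406, 1439.5672569848014, 3652.9615892901015, 135.9412077852908, 14.252200436130817, 29964.86884268204, 86.9378898519842, 2281.5105353716976, 1083.5506369602879, 434.93882766769445, 4323.942456751762, 390.6566211205997, 9.34337887940247, 375.42556395594295, 24.57443604412627, 12302.113129729174, 3641.23718385526, 362.7204519150385, 1394.7031563054177, 144.36664788418534, 0.13442302564429645, 0.010653155113717094, 38.75, 11834.007031276165, 416.8266441047392, 280899.5180010474, 1536.282619019792, 3779.2155451967933, 146.5610051992216, 16.89727823099625, 31280.743893147162, 87.425625572869, 1951.1252635131495, 1189.1158583632384, 659.7588781236892, 4422.5243852940075, 390.9588487759914, 9.04115122400058, 379.01392478490413, 20.986075215050082, 12255.85523859952, 3684.1841466254878, 359.9232706760309, 1396.6531040077641, 143.63749819793293, 0.12476032103452861, 0.010309374791344124, 35.0, 11731.04069126834, 412.24906773849017, 259421.24095074576, 1580.1964977426765, 3911.4929331859457, 162.10312260664844, 20.033461468803015, 32586.761183954284, 89.08454336444962, 1365.726292146573, 1157.122031460459, 1277.1516763928112, 4572.187769141988, 390.6548170625563, 9.345182937423717, 382.18335869272187, 17.816641307253708], "meta": {"scenario": "developing_IR", "note": "warm start only"}}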