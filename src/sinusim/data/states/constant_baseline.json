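{"y": [5030.0, 1014.7332079787598, 432.0, 1050.0, 19.21863836305708, 0.06000000000000001, 0.049999999999999975, 65.00097676511545, 5010.917123438406, 968.1739419575691, 424.6120831284704, 1050.1358962777074, 19.098753956665444, 0.05568000000000002, 0.04839999999999998, 61.250976765115446, 4893.475440649418, 79.9750218707908, 238193.4879301242, 163.79850826679254, 719.857856511219, 95.23456936283843, 12.31247728986547, 15169.42526014453, 16.15047628609697, 2805.574266682195, 790.6190304520788, 203.80670286572735, 3858.447386209924, 355.22857500410294, 44.77142499589681, 379.26728301089025, 20.73271698910975, 4986.4430228189785, 930.6194400418731, 417.81773372118084, 1050.2975718506948, 18.981987140620333, 0.05167104000000002, 0.04685119999999997, 57.50097676511545, 4836.381974514666, 89.72286969936648, 247549.62547284897, 164.34352187899486, 730.3287631581608, 96.96467297221452, 13.382872154096043, 15388.080697579693, 16.1140933431534, 2677.473039847199, 870.9676126660911, 251.55934748670867, 3899.8539459879394, 358.4076568797375, 41.59234312026203, 381.07412415247904, 18.925875847517112, 4956.801958949925, 901.6117383413916, 411.616969240918, 1050.4966711208215, 18.869024590596393, 0.04795072512000002, 0.04535196159999996, 53.75097676511545, 4775.808558614149, 99.00110266790739, 253490.6328906136, 164.07755786751173, 746.9039959388239, 100.07702912666406, 14.921309865002305, 15705.092800972854, 16.09759479126557, 2519.969462345017, 961.257685642821, 318.77285201216307, 3942.95679547812, 361.6077627370856, 38.392237262914406, 382.7529498708705, 17.247050129129043, 4922.3306243335865, 880.6132401859483, 406.0085176773392, 1050.749016606383, 18.76100774156429, 0.04449827291136003, 0.04390069882879996, 50.00097676511545, 4712.781494885148, 107.56714807159233, 256381.6142756611, 162.82523729735712, 768.6212500235832, 104.63259127937025, 17.088557669828553, 16155.691283738492, 16.112973488626544, 2312.0543717089336, 1063.3344020563707, 424.6112262346968, 3990.2168773136787, 364.5904771556903, 35.4095228443094, 384.3483164099987, 15.651683590002424, 4883.611363259173, 867.0599689014919, 400.9882443936045, 1051.0753050501337, 18.660075384688145, 0.04129439726174211, 0.04249587646627836, 46.250976765115446, 4649.341554123525, 115.27810360025673, 256056.1224136656, 160.33636542783776, 794.7758553843912, 111.04092065909927, 20.115710513161396, 16781.049607287332, 16.186260034712916, 2015.7342435112416, 1165.0046879135034, 619.2610685752547, 4045.2589513414127, 367.03140578838065, 32.96859421161938, 385.87318812053303, 14.126811879470727, 4842.006287701147, 860.495470789885, 396.5509948054544, 1051.5007288346226, 18.57140363285752, 0.03832120065889668, 0.04113600841935744, 42.500976765115446, 4591.426659911202, 122.78002220329893, 251989.378351669, 156.1467580259869, 825.4848141946482, 120.88507587912918, 24.440511822208617, 17619.49104293373, 16.395798735504044, 1554.6916846321892, 1183.3423023540145, 1061.9660130138047, 4114.319526383177, 368.0285120039151, 31.971487996086157, 387.2670759540342, 12.732924045971936, 4801.029688145642, 860.658215234598, 392.6984640846367, 1052.047011830907, 18.50776566744971, 0.03556207421145613, 0.039819656149938, 38.75097676511544, 4555.112550980727, 131.92723990093504, 242731.15700704555, 148.87175052448652, 861.5261856064002, 138.98684350200324, 31.162669816553812, 18642.952987442968, 16.93991981593884, 937.7925843072314, 941.7349668738792, 1920.4724488189072, 4208.859257210208, 364.86931483388514, 35.13068516611322, 388.39097294713974, 11.609027052862938, 4763.810340959914, 865.9609753103231, 389.3966509083373, 1052.6943580031636, 18.47617331864147, 0.03300160486823129, 0.03854542715313998, 35.00097676511544, 4540.969642851182, 142.43802940872735, 222893.42098359397, 136.71814299546585, 894.242362380857, 165.52872524731902, 40.63414251448162, 19501.876233814717, 17.693030171731483, 538.4718999234298, 685.1533718167893, 2576.374728259837, 4314.892402930953, 357.93361517714834, 42.06638482284991, 389.6613841262472, 10.338615873766793], "meta": {"scenario": "constant_baseline"}}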