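{"y": [12350.715173148337, 3552.1879301478475, 449.44201672979773, 1927.712976115535, 185.77011399736, 0.2259246688270612, 0.01348461987285254, 65.0, 12357.556933057625, 3478.606020890017, 443.0826774087582, 1929.2711107276787, 184.90652020568407, 0.20968510486111905, 0.013049429131798143, 61.25, 12403.706101607107, 233.89552959901934, 305329.51174002356, 950.8713004835857, 3084.745261108185, 99.50119599657403, 9.389157708404376, 31867.01336873025, 103.38325002405699, 2829.0300843256255, 774.9395946830755, 196.03032099110263, 3943.4771174758976, 387.0510528337822, 12.948947166260673, 354.20732149444393, 45.79267850552815, 12356.60826648009, 3420.2073290650437, 437.2119538856314, 1930.8900631627257, 184.04694809643038, 0.19461283516353886, 0.012628284019712542, 57.5, 12317.012036841212, 262.7521184371308, 307026.3491254748, 1022.7919903099507, 3107.3123801939378, 101.96455417852675, 10.409438689614415, 32436.799105170554, 103.24030560336163, 2733.9800544720956, 835.4394943773078, 230.58045115044678, 3991.7261763034585, 387.9535760932778, 12.04642390661083, 359.3173485471287, 40.68265145286505, 12347.577966951738, 3377.361439539708, 431.82295946572293, 1932.5913251308552, 183.19247024608896, 0.18062395594101374, 0.012220731197511062, 53.75, 12219.641841110284, 289.9082355313427, 306727.49698864267, 1090.6450693084928, 3147.40045335822, 105.07107122414078, 11.700049541590323, 33210.45871872194, 103.17621787758284, 2615.0980230740474, 906.4685797783599, 278.4333971478877, 4044.969688729763, 388.7434230442435, 11.256576955772301, 363.99035454026296, 36.00964545980641, 12330.17974996262, 3350.498238572413, 426.9056670428973, 1934.4013366488634, 182.34471353584436, 0.16764059424385372, 0.011826331958839968, 50.0, 12111.570346459885, 313.0032173807228, 304191.0437574124, 1158.681946105483, 3205.760253215632, 108.89545626101634, 13.296453492709347, 34239.54234249798, 103.2324271930131, 2460.499141135919, 990.2497143099672, 349.2511445537909, 4107.044474238049, 389.41719343408676, 10.58280656584229, 368.2836933178565, 31.71630668219918, 12304.18896382021, 3340.148858857977, 422.44556125926596, 1936.3504720184112, 181.50629206788884, 0.1555904744853143, 0.011444661757743632, 46.25, 11993.456140231905, 328.4427647452447, 298929.20207951945, 1230.0150412272353, 3283.461288693326, 113.66126419937224, 15.220926774320093, 35570.0256202424, 103.48323876652051, 2251.848714361293, 1085.035772875803, 463.11551276284035, 4183.100430334899, 389.96225864166104, 10.037741358379028, 372.241294316181, 27.758705683846802, 12269.808022214842, 3346.6008481834747, 418.4234567036543, 1938.466737253274, 180.68210721417395, 0.1444065161179874, 0.011075309751579554, 42.5, 11870.254551516871, 334.0974668629194, 290352.2601769534, 1299.9729305923981, 3379.488683928098, 119.86723717062218, 17.48378268792379, 37192.03707658713, 104.10213961230019, 1953.2549016579474, 1173.8615017757197, 672.8835965661793, 4282.167611905556, 390.33922497097524, 9.66077502901781, 375.88493514309636, 24.115064856978353, 12229.181790564255, 3368.376085879963, 414.8192598616874, 1940.7532907028153, 179.88552198651007, 0.134026460227827, 0.010717878358688239, 38.75, 11764.644978879347, 337.5729635846937, 277364.0945655213, 1335.2956935124325, 3482.942170198998, 129.03687984736706, 20.154174067250622, 38875.10543085772, 105.73842247983069, 1470.3126635397032, 1165.753374593133, 1163.933961867338, 4425.466452992776, 390.23352663236085, 9.766473367638666, 379.1364839831447, 20.863516016802425, 12191.603835694405, 3397.7070396616164, 411.629553642276, 1943.1347936872046, 179.16458654185476, 0.12439252296733157, 0.010371982830341728, 35.0, 11760.493967230224, 361.730888261641, 256706.64529478297, 1228.4539530917382, 3552.5144777327496, 147.91749300173305, 23.816075389790317, 39833.31200315564, 111.18431490877707, 763.9846083613128, 834.2490832270807, 2201.766308411278, 4516.275821460076, 387.97407699562757, 12.025923004338887, 381.68121286945683, 18.31878713052192], "meta": {"scenario": "NAFLD"}}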