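{"y": [2161.3539694776946, 1454.7804835782943, 284.0917182711301, 998.3118801935736, 191.33932604329115, 0.024297123005832314, 0.07164539676710577, 65.0, 2191.5515045541647, 1409.6371928914762, 279.40311981752865, 999.7829176405996, 190.5839685161117, 0.022550719290174354, 0.06934873604733803, 61.25, 2332.4464715391623, 165.0403859609121, 242902.52663914487, 404.35732450861076, 1166.9574635027154, 70.8881956228604, 4.841261751781603, 25604.144973181432, 111.91968781709822, 2436.275452121044, 1020.5991584020786, 343.12538947680997, 4314.292481223796, 373.7237297238217, 26.276270276187766, 354.9104538970092, 45.08954610299585, 2217.053425733741, 1374.3424109194095, 275.09098268912754, 1001.3174989336808, 189.8329240570372, 0.020929844045341508, 0.0671256937376492, 57.5, 2335.8813770094707, 165.83979675752258, 260062.447773747, 382.5867361858296, 1184.2767649757538, 75.47843978669016, 5.35199977754222, 26172.835888454774, 111.86687136729988, 2364.2979879553704, 1057.3860563886128, 378.3159556559973, 4336.872700331975, 378.3868426166135, 21.61315738336822, 359.1366143371723, 40.86338566283833, 2237.1549788493644, 1347.0448445603713, 271.15755412923403, 1002.9161016844803, 189.0878213011167, 0.019425474342572753, 0.06497391013347018, 53.75, 2330.4335479640417, 161.05660989796797, 269360.9637836335, 356.20973835308104, 1199.7110821213087, 80.58865095362793, 6.0710143483271795, 26748.62086392187, 111.94532754207522, 2241.9638014702305, 1113.9134845675335, 444.1227139625373, 4368.7122761814235, 381.82896818962377, 18.1710318103603, 363.3029713053036, 36.697028694712884, 2251.785898557368, 1326.2377786175668, 267.61091581237383, 1004.5793886610566, 188.3513115622724, 0.018029235828429017, 0.06289110116317324, 50.0, 2319.1062234498604, 152.910994528839, 274096.47176985454, 327.75272889202165, 1213.5916405663254, 86.51985166061773, 7.112367299126141, 27333.31420590173, 112.23884775477784, 2052.4207781658733, 1184.6270999656679, 562.9521218684838, 4416.933876462583, 384.4345865128188, 15.565413487192298, 367.3561984807149, 32.643801519333074, 2261.4086505376795, 1310.6072065219182, 264.46699030911327, 1006.3113214508558, 187.62860245791518, 0.016733356103875413, 0.060875055963991745, 46.25, 2304.9467129952523, 143.83081357267022, 275368.2807315854, 297.770264816767, 1225.6316459593138, 93.76932030147661, 8.676816411591425, 27956.483650474805, 112.95838449993818, 1763.394896355628, 1243.6831916643478, 792.9219119799554, 4498.458778548486, 386.31316638209364, 13.686833617915799, 371.2226287923768, 28.777371207633266, 2267.20043379612, 1299.204998342872, 261.7533096198761, 1008.1182227182023, 186.9316586521093, 0.015530621454627662, 0.0589236345356297, 42.5, 2292.56149225641, 138.10244423170073, 273180.61553107994, 266.6051503768356, 1236.8366796829473, 103.72677001818734, 11.16251440225933, 28639.96701926832, 114.67242400014752, 1334.1366929562155, 1195.3533854297582, 1270.509921613703, 4632.936352632626, 387.174790581547, 12.825209418476968, 374.73052251684123, 25.269477483188282, 2271.107593807102, 1292.25916132244, 259.5133141459238, 1010.0054866069055, 186.28864215988395, 0.014414336691858468, 0.05703476546907193, 38.75, 2287.5505548970664, 139.57064419852088, 266543.6233123384, 235.85515669466963, 1253.7067503606195, 120.4757650977851, 15.441843266397436, 29376.592402383612, 118.81712649579396, 819.9635211608974, 925.0855436823983, 2054.950935156806, 4699.344270137761, 386.1788763011399, 13.82112369887952, 377.63352560643983, 22.366474393541985, 2274.6484111928453, 1289.4352706978239, 257.75178888749645, 1011.9662017543791, 185.73348373542566, 0.013378287879677575, 0.05520644374818446, 35.0, 2289.381288698756, 145.5713336088364, 252473.55846352933, 203.583809182676, 1272.8948577415538, 145.7761551795154, 22.177349519988187, 30055.95020786756, 126.22280131591964, 471.0034564367702, 655.3596616226156, 2673.636881940367, 4545.087903557974, 383.3086713652123, 16.6913286347746, 380.54561806594336, 19.45438193407269], "meta": {"scenario": "MH"}}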