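"""Null quantiles of the dip statistic under the uniform distribution.

Generated by scripts/make_dip_table.py (seed 20240817); do not edit by hand.
"""

import numpy as np

N_GRID = np.array([4, 5, 6, 7, 8, 10, 12, 15, 20, 25, 30, 40, 50, 75, 100, 150, 200, 300, 500, 750, 1000, 1500, 2000, 3000, 5000, 7500, 10000, 15000, 25000, 50000])

P_GRID = np.array([0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98, 0.99, 0.995, 0.998, 0.999, 0.9995, 0.9999, 1.0])

QUANTILES = np.array([
    [0.125, 0.125, 0.125, 0.125, 0.125, 0.125, 0.125, 0.125, 0.125, 0.125, 0.125, 0.132284, 0.15764, 0.188632, 0.208029, 0.224376, 0.231557, 0.237019, 0.242362, 0.24559, 0.247043, 0.248442, 0.249421],
    [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.109236, 0.122062, 0.134003, 0.14693, 0.160933, 0.176482, 0.186694, 0.193345, 0.196295, 0.197928, 0.199084, 0.19947, 0.199728, 0.199935, 0.199973],
    [0.0833333, 0.0833333, 0.0833333, 0.0833333, 0.0833333, 0.0833333, 0.0924714, 0.103629, 0.113429, 0.122611, 0.131369, 0.140047, 0.149076, 0.159075, 0.164571, 0.178101, 0.192261, 0.202405, 0.214298, 0.220684, 0.224397, 0.234671, 0.239759],
    [0.0714286, 0.0714286, 0.0714286, 0.0714286, 0.0724857, 0.0818282, 0.0938667, 0.103361, 0.110945, 0.117557, 0.124224, 0.130483, 0.136944, 0.144914, 0.160716, 0.175924, 0.184581, 0.190728, 0.196988, 0.201697, 0.203554, 0.207747, 0.208429],
    [0.0625, 0.0625, 0.0625, 0.0655425, 0.0740557, 0.0822801, 0.0924173, 0.0997924, 0.1059, 0.111151, 0.116169, 0.120619, 0.125468, 0.14189, 0.154441, 0.166133, 0.173916, 0.18015, 0.190248, 0.197735, 0.205991, 0.216775, 0.225858],
    [0.05, 0.0571716, 0.0615756, 0.0654773, 0.0721882, 0.0782098, 0.0853556, 0.0902602, 0.0943143, 0.0977066, 0.102227, 0.11001, 0.118881, 0.130532, 0.139905, 0.151215, 0.159504, 0.167215, 0.175293, 0.18115, 0.185179, 0.190563, 0.200269],
    [0.0425504, 0.0558753, 0.0586722, 0.0623989, 0.0677161, 0.0723252, 0.0777375, 0.081346, 0.0854212, 0.0909795, 0.096637, 0.10289, 0.110157, 0.119728, 0.129454, 0.141394, 0.148628, 0.155596, 0.165147, 0.169793, 0.175479, 0.184558, 0.209309],
    [0.0412918, 0.0524572, 0.0547571, 0.057249, 0.0611577, 0.0642159, 0.0691536, 0.0744062, 0.0791548, 0.0835834, 0.0879726, 0.0929666, 0.0993713, 0.109824, 0.119065, 0.129531, 0.13544, 0.142723, 0.14967, 0.156625, 0.161913, 0.17113, 0.201451],
    [0.0385056, 0.0459161, 0.0475607, 0.0489113, 0.0524368, 0.0566986, 0.0619231, 0.0659821, 0.0696022, 0.0733973, 0.0776047, 0.082558, 0.0884722, 0.0972373, 0.10495, 0.114354, 0.120972, 0.126475, 0.131765, 0.137182, 0.141566, 0.150308, 0.153865],
    [0.0342438, 0.0406251, 0.0426046, 0.0447769, 0.0483918, 0.0516673, 0.0559809, 0.0595799, 0.0631679, 0.0665642, 0.0702052, 0.0746829, 0.0801323, 0.0885188, 0.0954721, 0.104694, 0.110667, 0.115936, 0.12286, 0.127192, 0.132004, 0.144499, 0.149524],
    [0.0311161, 0.037982, 0.0397347, 0.0416761, 0.0445743, 0.0474283, 0.0515863, 0.055066, 0.0582047, 0.0613391, 0.064877, 0.0687485, 0.0738191, 0.0810244, 0.0876589, 0.0951682, 0.100989, 0.106323, 0.110811, 0.115411, 0.11729, 0.124855, 0.130129],
    [0.0286306, 0.03352, 0.0346698, 0.0361226, 0.0388662, 0.0417266, 0.0454929, 0.0485153, 0.0512729, 0.0540609, 0.0570609, 0.0604326, 0.0649548, 0.0714642, 0.0772946, 0.0840006, 0.0888154, 0.09336, 0.09971, 0.103198, 0.105877, 0.112458, 0.116445],
    [0.0235123, 0.029879, 0.0309789, 0.0327125, 0.035127, 0.0375959, 0.0409346, 0.0436006, 0.0462507, 0.0487714, 0.0515618, 0.0548027, 0.0588381, 0.0650294, 0.0705624, 0.0767331, 0.0814809, 0.0859166, 0.0905533, 0.0932237, 0.0948279, 0.101062, 0.109792],
    [0.0207226, 0.0250857, 0.026056, 0.0272677, 0.0293088, 0.031347, 0.034222, 0.0363683, 0.0384664, 0.0406399, 0.0429354, 0.045654, 0.0491001, 0.0542003, 0.0589084, 0.0640136, 0.0674078, 0.0705625, 0.0756579, 0.0778696, 0.0800591, 0.0837978, 0.091798],
    [0.0176875, 0.0219691, 0.022802, 0.0239466, 0.0256961, 0.0274516, 0.0297557, 0.0317013, 0.0335333, 0.035475, 0.0374451, 0.0398303, 0.0427448, 0.0470497, 0.0512253, 0.0560427, 0.0592122, 0.0623786, 0.0658829, 0.0681426, 0.0704203, 0.0765349, 0.0824434],
    [0.0134555, 0.0183205, 0.0189207, 0.0197881, 0.0212185, 0.0226941, 0.0247358, 0.0263192, 0.0277259, 0.0292145, 0.0308279, 0.0327918, 0.0352285, 0.0389187, 0.0422251, 0.0462139, 0.0490572, 0.0513843, 0.0536231, 0.0554536, 0.0572989, 0.0618598, 0.0627928],
    [0.0135392, 0.0157981, 0.0164555, 0.0174182, 0.0186444, 0.0198979, 0.0215831, 0.022992, 0.0243679, 0.0256462, 0.02704, 0.0286829, 0.030798, 0.0339141, 0.0366651, 0.0400232, 0.0423124, 0.0447048, 0.0471966, 0.0485575, 0.0501472, 0.0520901, 0.0524092],
    [0.0113686, 0.012987, 0.0136094, 0.0142009, 0.0152463, 0.0162718, 0.0176445, 0.0188369, 0.0199153, 0.0211003, 0.0222332, 0.0235753, 0.0253131, 0.0279554, 0.0304003, 0.0333049, 0.0354654, 0.0374445, 0.0402712, 0.0420274, 0.0426966, 0.0487013, 0.0490114],
    [0.00859649, 0.0102358, 0.0106513, 0.011082, 0.0119492, 0.012756, 0.0139053, 0.0148419, 0.015656, 0.0165511, 0.017453, 0.0185944, 0.0199903, 0.0220381, 0.0237732, 0.0259009, 0.027487, 0.0290688, 0.030398, 0.0317084, 0.0325061, 0.0345018, 0.0371436],
    [0.00695336, 0.00851383, 0.00881653, 0.00919857, 0.009843, 0.0105132, 0.0113973, 0.0121264, 0.0128538, 0.0135602, 0.014349, 0.0152387, 0.0163533, 0.0180167, 0.0195177, 0.0213355, 0.0226462, 0.0239927, 0.0258755, 0.0274554, 0.0283725, 0.0295735, 0.0316925],
    [0.00623097, 0.00727071, 0.00757169, 0.00793066, 0.00852079, 0.00912294, 0.00987034, 0.0104985, 0.011124, 0.0117208, 0.0123723, 0.0130987, 0.0140696, 0.0155667, 0.0168518, 0.0183623, 0.019487, 0.0204062, 0.0214192, 0.0221582, 0.0234754, 0.0240552, 0.0245574],
    [0.00509572, 0.00606393, 0.00625318, 0.00656353, 0.00698527, 0.00743757, 0.00803112, 0.00861305, 0.00911067, 0.00959676, 0.0101408, 0.0107882, 0.0116023, 0.0127447, 0.0139165, 0.0150664, 0.0161366, 0.0166267, 0.0173325, 0.0182679, 0.0192093, 0.0194257, 0.0194829],
    [0.0047369, 0.005192, 0.00541456, 0.0056662, 0.00606096, 0.00647243, 0.00704041, 0.00753017, 0.00798262, 0.00839296, 0.00881474, 0.00937067, 0.0100342, 0.0111374, 0.0121403, 0.0133485, 0.0141184, 0.0147602, 0.0155266, 0.0163101, 0.0171405, 0.0181144, 0.0186098],
    [0.00354641, 0.00426047, 0.00443396, 0.00465113, 0.00493928, 0.00528239, 0.0057408, 0.006108, 0.00648702, 0.00685876, 0.00724544, 0.00769744, 0.00824442, 0.00908662, 0.00983804, 0.0109569, 0.0116565, 0.0122308, 0.0126049, 0.0132359, 0.0134237, 0.0139198, 0.0139439],
    [0.00272582, 0.00329296, 0.00343881, 0.00360949, 0.00389675, 0.00414441, 0.00448779, 0.00478462, 0.00502735, 0.00531316, 0.00561847, 0.00591677, 0.00637264, 0.00702071, 0.00758144, 0.00824602, 0.00872774, 0.00957988, 0.0101494, 0.0104593, 0.0105523, 0.0115902, 0.0118234],
    [0.00235744, 0.00267309, 0.00273932, 0.00289664, 0.00313395, 0.0033447, 0.00366086, 0.00389042, 0.00410918, 0.00433747, 0.00457717, 0.00485393, 0.00519358, 0.00573835, 0.00624173, 0.00678142, 0.00705595, 0.00738206, 0.00768987, 0.00797993, 0.00801442, 0.00899964, 0.00924594],
    [0.00209703, 0.00236922, 0.00244777, 0.00255148, 0.00275428, 0.00292749, 0.00316589, 0.00335426, 0.00354154, 0.00373017, 0.00393418, 0.00421493, 0.00452604, 0.00498905, 0.00536987, 0.00595151, 0.00632238, 0.00700843, 0.00725582, 0.00759651, 0.00786199, 0.00809975, 0.00815919],
    [0.00179317, 0.00201807, 0.00206703, 0.00212726, 0.00228882, 0.00241295, 0.00262569, 0.0027727, 0.00292835, 0.00308532, 0.00323435, 0.00343518, 0.00369014, 0.00413011, 0.00444114, 0.00484834, 0.00519799, 0.00536693, 0.00546328, 0.00549041, 0.00554221, 0.00558364, 0.005594],
    [0.00137535, 0.00151563, 0.00155409, 0.00161844, 0.0017479, 0.00187212, 0.00200689, 0.00212178, 0.00222034, 0.00234685, 0.00249782, 0.00265494, 0.00285635, 0.00314935, 0.00345178, 0.00378928, 0.00388914, 0.00404922, 0.00409696, 0.00415538, 0.00424335, 0.00431373, 0.00433133],
    [0.000955377, 0.00106155, 0.00110607, 0.00117302, 0.00125415, 0.00132622, 0.00144754, 0.00153367, 0.00163018, 0.00173143, 0.00181755, 0.00194135, 0.00202412, 0.00221299, 0.00239044, 0.00263653, 0.00273738, 0.00288304, 0.00311048, 0.00344687, 0.00361507, 0.00374963, 0.00378327],
])
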