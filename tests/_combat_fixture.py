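"""Frozen oracle fixture for the empirical-Bayes batch correction.

Expected values were computed once with Bioconductor sva::ComBat 3.50
(parametric priors, group covariate protected) on the 8-feature x 10-sample
input below: two batches of 5 samples, alternating A/B group labels, and a
planted +1.0 shift on the second batch.
"""

import numpy as np

# features x samples
COMBAT_INPUT = np.array([
    [6.370958, 7.018424, 4.715747, 6.895193, 6.035104,
     6.205999, 5.568554, 6.679289, 5.272708, 6.623518],
    [4.435302, 4.937286, 2.343545, 4.569531, 4.391074,
     5.638943, 6.655648, 6.089833, 7.302543, 5.046477],
    [5.363128, 6.304870, 2.559533, 4.742731, 5.504955,
     6.758163, 6.321925, 3.006910, 6.335848, 5.457171],
    [5.632863, 7.286645, 6.320113, 3.236837, 3.282991,
     5.273295, 5.216161, 6.284883, 7.038506, 6.580996],
    [5.404268, 3.611139, 4.693361, 5.460097, 4.215541,
     4.631719, 7.575728, 5.632765, 6.920729, 6.768179],
    [4.893875, 4.721211, 3.218692, 4.360005, 4.149092,
     6.432818, 6.642899, 6.185231, 6.720878, 6.463768],
    [6.511522, 4.866679, 4.828083, 5.455450, 2.585792,
     5.188607, 6.089761, 6.581824, 4.956881, 5.114224],
    [4.905341, 5.635950, 6.214675, 5.704837, 5.036123,
     7.444101, 6.276551, 7.399737, 5.909814, 4.900219],
])

COMBAT_EXPECTED = np.array([
    [6.1524881982087249, 6.9206828268452236, 4.8827130205973299,
     6.8261476498120652, 5.8948418482862692, 6.2052414489823082,
     5.7333278525757470, 6.8267771054172375, 5.3448158666608778,
     6.7535373050939000],
    [5.3263373466893436, 5.6928787817417792, 3.6508463529543844,
     5.3983081454771460, 5.2909108532338847, 4.6335946619999824,
     5.7535783556366242, 5.1400487318973438, 6.4801915108324684,
     3.9681179005375182],
    [5.7777411259308069, 6.5333971808594757, 3.4733036478757535,
     5.2493844552227689, 5.8943169702307561, 6.3187116990789800,
     5.8669917873843618, 2.4598449978602108, 5.8813142020764850,
     4.9803976191296915],
    [6.0910671618312566, 7.3916932945626703, 6.6268822130991465,
     4.2342570178873542, 4.2589874438931270, 4.5116660458819577,
     4.4529141535313990, 5.7932190742039689, 6.7615929371839094,
     6.1683564936627961],
    [6.1715685576910149, 4.5377060721812068, 5.5878688013886642,
     6.0558179124265310, 5.1955482621952260, 3.7462741443696412,
     6.7589141007987816, 4.7809822416523513, 6.0818894995196411,
     5.9545767213946919],
    [5.6627459032153791, 5.5473937938201399, 4.3897462642026381,
     5.2729073003389884, 5.0967728183984802, 5.4371825362971355,
     5.7251972640803217, 5.1197186094069753, 5.8251844183128458,
     5.4768676107850949],
    [6.5565090138331428, 5.3340933209688117, 5.2364619759552511,
     5.7957705272937234, 3.4781983307561957, 4.6589809997485636,
     5.8400429708975476, 6.3736298822035895, 4.4457939587510911,
     4.5674369489483997],
    [5.4011007825975401, 6.0848846397158658, 6.5322176540051178,
     6.1443952366457966, 5.5140816772175727, 6.9284977244144521,
     5.8305388918817034, 6.8880869996157275, 5.4964818190183511,
     4.6113010013410536],
])
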