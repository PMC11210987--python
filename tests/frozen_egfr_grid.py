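"""Frozen eGFR oracle values.

Each tuple is (creatinine µmol/L, age, sex, expected eGFR). The expected
values were produced before the build by an independent exp/log evaluation
of the published piecewise formulas (see tests/oracles for the estimator
counterparts); they are frozen here so the test cannot drift with the
implementation.
"""

GRID_2009 = [
    (40.0, 18.0, 'female', 146.0252638292149),
    (40.0, 18.0, 'male', 164.8484470956678),
    (40.0, 45.0, 'female', 120.79743397747036),
    (40.0, 45.0, 'male', 136.36865897134885),
    (40.0, 60.0, 'female', 108.71674382707425),
    (40.0, 60.0, 'male', 122.7307242817332),
    (40.0, 82.0, 'female', 93.14936599079128),
    (40.0, 82.0, 'male', 105.1566552859452),
    (61.894, 18.0, 'female', 126.48917604450742),
    (61.894, 18.0, 'male', 137.7729515444216),
    (61.894, 45.0, 'female', 104.63646831668362),
    (61.894, 45.0, 'male', 113.9708197174224),
    (61.894, 60.0, 'female', 94.17200139430383),
    (61.894, 60.0, 'male', 102.57284449677634),
    (61.894, 82.0, 'female', 80.68731563480439),
    (61.894, 82.0, 'male', 87.88522445028667),
    (70.0, 18.0, 'female', 109.00161455545808),
    (70.0, 18.0, 'male', 130.97735694678212),
    (70.0, 45.0, 'female', 90.17011846046265),
    (70.0, 45.0, 'male', 108.34925555640099),
    (70.0, 60.0, 'female', 81.15239990405253),
    (70.0, 60.0, 'male', 97.51348081099465),
    (70.0, 82.0, 'female', 69.53201810125512),
    (70.0, 82.0, 'male', 83.55032162798531),
    (79.578, 18.0, 'female', 93.34642717757204),
    (79.578, 18.0, 'male', 124.25262872741396),
    (79.578, 45.0, 'female', 77.21957542362983),
    (79.578, 45.0, 'male', 102.78631465293086),
    (79.578, 60.0, 'female', 69.49701267107997),
    (79.578, 60.0, 'male', 92.50687759754797),
    (79.578, 82.0, 'female', 59.545590133402555),
    (79.578, 82.0, 'male', 79.26062439568211),
    (88.42, 18.0, 'female', 82.18203553866621),
    (88.42, 18.0, 'male', 109.39180275667223),
    (88.42, 45.0, 'female', 67.98398271498284),
    (88.42, 45.0, 'male', 90.49289639791655),
    (88.42, 60.0, 'female', 61.18505161746657),
    (88.42, 60.0, 'male', 81.44289751798158),
    (88.42, 82.0, 'female', 52.4238361603828),
    (88.42, 82.0, 'male', 69.78091875451945),
    (120.0, 18.0, 'female', 56.81020216442466),
    (120.0, 18.0, 'male', 75.6195729273887),
    (120.0, 45.0, 'female', 46.995475065396626),
    (120.0, 45.0, 'male', 62.555273851682614),
    (120.0, 60.0, 'female', 42.29555923074727),
    (120.0, 60.0, 'male', 56.29925618812613),
    (120.0, 82.0, 'female', 36.239169679665466),
    (120.0, 82.0, 'male', 48.23764799301395),
    (200.0, 18.0, 'female', 30.634528220292278),
    (200.0, 18.0, 'male', 40.77735780882692),
    (200.0, 45.0, 'female', 25.342001124200983),
    (200.0, 45.0, 'male', 33.73252037707987),
    (200.0, 60.0, 'female', 22.807602393268),
    (200.0, 60.0, 'male', 30.35900395997263),
    (200.0, 82.0, 'female', 19.541734124066817),
    (200.0, 82.0, 'male', 26.011834713165136),
    (400.0, 18.0, 'female', 13.251527181068045),
    (400.0, 18.0, 'male', 17.638994192764226),
    (400.0, 45.0, 'female', 10.962147492696145),
    (400.0, 45.0, 'male', 14.591620522058781),
    (400.0, 60.0, 'female', 9.865846827345067),
    (400.0, 60.0, 'male', 13.132344107693635),
    (400.0, 82.0, 'female', 8.45313559419345),
    (400.0, 82.0, 'male', 11.251896299895702),
]

GRID_2021 = [
    (40.0, 18.0, 'female', 142.7386427983275),
    (40.0, 18.0, 'male', 156.2743072591573),
    (40.0, 45.0, 'female', 120.67418047073674),
    (40.0, 45.0, 'male', 132.11750922821494),
    (40.0, 60.0, 'female', 109.92570110805188),
    (40.0, 60.0, 'male', 120.34976971799588),
    (40.0, 82.0, 'female', 95.86875274992998),
    (40.0, 82.0, 'male', 104.95982468435156),
    (61.894, 18.0, 'female', 128.48449451683896),
    (61.894, 18.0, 'male', 136.9720127265977),
    (61.894, 45.0, 'female', 108.62343073362948),
    (61.894, 45.0, 'male', 115.79895296162347),
    (61.894, 60.0, 'female', 98.94831465668567),
    (61.894, 60.0, 'male', 105.4847113295425),
    (61.894, 82.0, 'female', 86.29511949639256),
    (61.894, 82.0, 'male', 91.99566259222074),
    (70.0, 18.0, 'female', 110.84378133931712),
    (70.0, 18.0, 'male', 131.97452018064928),
    (70.0, 45.0, 'female', 93.7096094734366),
    (70.0, 45.0, 'male', 111.57397011487603),
    (70.0, 60.0, 'female', 85.36287117713019),
    (70.0, 60.0, 'male', 101.63604875908628),
    (70.0, 82.0, 'female', 74.44693923635097),
    (70.0, 82.0, 'male', 88.63915472676442),
    (79.578, 18.0, 'female', 95.03363845054471),
    (79.578, 18.0, 'male', 126.96096296130331),
    (79.578, 45.0, 'female', 80.3433899352317),
    (79.578, 45.0, 'male', 107.33540586327024),
    (79.578, 60.0, 'female', 73.18718414805923),
    (79.578, 60.0, 'male', 97.77501448289098),
    (79.578, 82.0, 'female', 63.82824026436842),
    (79.578, 82.0, 'male', 85.27185720987407),
    (88.42, 18.0, 'female', 83.7468283122504),
    (88.42, 18.0, 'male', 111.8822570705995),
    (88.42, 45.0, 'female', 70.80128881345036),
    (88.42, 45.0, 'male', 94.58755818693466),
    (88.42, 60.0, 'female', 64.4950003539451),
    (88.42, 60.0, 'male', 86.16262077966914),
    (88.42, 82.0, 'female', 56.24758523451536),
    (88.42, 82.0, 'male', 75.14441940827453),
    (120.0, 18.0, 'female', 58.051237969209446),
    (120.0, 18.0, 'male', 77.55402396281043),
    (120.0, 45.0, 'female', 49.07770895050256),
    (120.0, 45.0, 'male', 65.56576481634927),
    (120.0, 60.0, 'female', 44.706345169413936),
    (120.0, 60.0, 'male', 59.7258057855268),
    (120.0, 82.0, 'female', 38.98944021459266),
    (120.0, 82.0, 'male', 52.08826006954253),
    (200.0, 18.0, 'female', 31.447996766833366),
    (200.0, 18.0, 'male', 42.01320730026445),
    (200.0, 45.0, 'female', 26.58678240794133),
    (200.0, 45.0, 'male', 35.51882840212904),
    (200.0, 60.0, 'female', 24.218691065475173),
    (200.0, 60.0, 'male', 32.35515749441893),
    (200.0, 82.0, 'female', 21.12168202958051),
    (200.0, 82.0, 'male', 28.21768306001995),
    (400.0, 18.0, 'female', 13.688535649950735),
    (400.0, 18.0, 'male', 18.28731064056102),
    (400.0, 45.0, 'female', 11.5725692007324),
    (400.0, 45.0, 'male', 15.460468036545898),
    (400.0, 60.0, 'female', 10.541797574672108),
    (400.0, 60.0, 'male', 14.083400291150603),
    (400.0, 82.0, 'female', 9.193746094306464),
    (400.0, 82.0, 'male', 12.282459941405932),
]

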