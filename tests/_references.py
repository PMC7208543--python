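"""Fixed vectors with independently computed reference statistics.

References: R 4.3 ``shapiro.test`` / ``cor.test`` and the two-way
absolute-agreement ICC mean-squares formula evaluated by hand.
"""

X10 = [27.438, 16.68, 31.004, 32.525, 9.392, 14.583, 26.023, 22.47, 24.866, 18.176]
A10 = [34.794, 33.778, 26.66, 37.272, 30.675, 17.407, 29.688, 16.411, 34.785, 25.501]
B10 = [34.624, 32.616, 29.305, 37.163, 30.018, 16.903, 30.953, 17.342, 35.81, 26.563]
X8 = [2.142, -0.406, -0.512, -0.814, 0.616, 1.129, -0.114, -0.84]
Y8 = [0.247, 0.448, 0.487, 0.136, -0.358, 0.797, 0.06, -0.201]

SHAPIRO_W_X10 = 0.9677060724  # R shapiro.test
SHAPIRO_P_X10 = 0.8687998219
PEARSON_R_X8Y8 = 0.208996502117  # R cor.test
PEARSON_P_X8Y8 = 0.619393117504
ICC_A1_AB = 0.9866153803  # mean-squares formula / pingouin ICC2
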