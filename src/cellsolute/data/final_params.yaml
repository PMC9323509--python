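# Final calibrated cell-solute model constants, modeling units
# (kg/m^3, cell/m^3, m, s).  Values reproduced verbatim from the published
# calibration; four entries (D_c_gel, D_s_med, D_s_gel, M_s) fall outside the
# literature search intervals — see docs/methods.md.
D_c_gel: 4.98e-10    # m^2/s
D_c_med: 2.0e-9      # m^2/s
M_c: 5.88e-20        # kg/cell/s
c_half: 5.13e-4      # kg/m^3  (1.65e-8 mol/mL)
D_s_gel: 2.67e-10    # m^2/s
D_s_med: 9.0e-11     # m^2/s
M_s: 1.75e-18        # kg/cell/s
s_half: 1.39         # kg/m^3  (7.8 mM)
A: 4.6               # dimensionless
D_v_gel: 4.16e-11    # m^2/s
D_v_med: 1.32e-10    # m^2/s
K_v: 8.37e-5         # 1/s
alpha: 2.92e-21      # kg/cell/s per (kg O2/m^3)
beta: 2.86e-22       # kg/cell/s
c_tau: 4.49e-4       # kg/m^3  (1.40e-8 mol/mL)
n_tau: 2.32e13       # cell/m^3
delta_0: 3.18e-6     # 1/s
delta_c: 2.53e-6     # 1/s
delta_s: 5.6e-7      # 1/s
n_max: 6.0e13        # cell/m^3 (metadata; enters no equation)
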