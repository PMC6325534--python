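# Class-2 excitable FSI unit (the configuration used by the network model)
k1: 200.0        # 1/s, fast ionic-current decay
k2: 20.0         # 1/s, slow ionic-current decay
a: 5.0           # 1/s, threshold-voltage coupling
b: 10.0          # 1/s, threshold relaxation
C: 1.0           # normalized capacitance (currents in V/s)
G: 50.0          # 1/s, membrane leak rate
E_L: -0.07       # V, leak reversal / resting potential
Theta_inf: -0.05 # V, threshold target
V_r: -0.07       # V, membrane reset
Theta_r: -0.06   # V, threshold floor after a spike
R1: 0.0          # multiplicative current reset on spike
R2: 1.0
A1: 0.0          # additive current increment on spike (V/s)
A2: 0.0
t_hold: 0.001    # s, spike hold (action-potential width)
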