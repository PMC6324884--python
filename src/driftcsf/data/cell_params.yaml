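# Receptive-field parameters of modeled magnocellular (M) and parvocellular
# (P) retinal ganglion cells, from neurophysiological fits in the macaque.
#
# Spatial kernel: difference of Gaussians,
#   K(f) = C * (Kc*pi*rc^2*exp(-pi*(rc*gamma*f)^2)
#             - Ks*pi*rs^2*exp(-pi*(rs*gamma*f)^2))
# radii in deg, f in cycles/deg; gamma = 0.5 scales radii down to model the
# smaller foveal receptive fields (cortical magnification).
#
# Temporal kernel: cascade of N first-order low-pass stages and one subtractive
# high-pass stage,
#   H(w) = A*exp(-i*rho*2*pi*w*delay) * (1 - Hs/(1 + i*rho*2*pi*w*tau_highpass))
#          * (1 + i*rho*2*pi*w*tau_lowpass)^-N
# time constants and the pure delay in ms, w in Hz; rho = 1/1.6 accounts for
# the speeding of responses with large stimuli.
M:
  dog:
    C: 1.0
    Kc: 148.0
    rc: 0.10
    Ks: 1.1
    rs: 0.72
    gamma: 0.5
  temporal:
    N: 30
    A: 499.77
    delay_ms: 2.0
    Hs: 1.0
    tau_lowpass_ms: 1.1
    tau_highpass_ms: 2.23
    rho: 0.625
P:
  dog:
    C: 1.0
    Kc: 353.2
    rc: 0.03
    Ks: 4.4
    rs: 0.18
    gamma: 0.5
  temporal:
    N: 38
    A: 67.59
    delay_ms: 3.5
    Hs: 0.69
    tau_lowpass_ms: 1.27
    tau_highpass_ms: 29.36
    rho: 0.625
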