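# Default gap gene-circuit configuration.
#
# Units: concentrations a.u.; rates 1/min; positions EL (fraction of egg
# length).  Any well-formed set with the same schema runs the model; this
# default is the package's hand-tuned set producing the canonical trunk
# pattern (anterior + posterior Hb, central Kr, abdominal Kni, posterior Gt).
circuit:
  genes: [Hb, Kr, Gt, Kni]
  R: {Hb: 20.0, Kr: 20.0, Gt: 20.0, Kni: 20.0}        # max synthesis, a.u./min
  D: {Hb: 0.2, Kr: 0.2, Gt: 0.2, Kni: 0.2}            # nn-exchange, 1/min
  delta: {Hb: 0.12, Kr: 0.12, Gt: 0.12, Kni: 0.12}    # degradation, 1/min
  # Interconnectivity T[target][regulator]; activation > 0, repression < 0.
  # Anterior Hb is maintained by autoactivation from its maternal initial
  # step; Hb represses Kr (sets Kr1), Kr represses kni (sets Kni2), kni
  # represses Kr (sets Kr2); the kni/gt interface is biased posteriorly by
  # the stronger Tll repression of kni.
  T:
    Hb:  {Hb: 0.035,  Kr: 0.0,   Gt: 0.0,   Kni: -0.02}
    Kr:  {Hb: -0.07,  Kr: 0.004, Gt: 0.0,   Kni: -0.04}
    Gt:  {Hb: -0.02,  Kr: -0.03, Gt: 0.010, Kni: -0.02}
    Kni: {Hb: -0.035, Kr: -0.05, Gt: -0.01, Kni: 0.010}
  # Strength of regulation by the Bcd gradient (Kr, kni and gt read Bcd
  # directly; anterior Hb is anchored by its initial domain).
  m: {Hb: 0.02, Kr: 0.18, Gt: 0.04, Kni: 0.12}
  # Strengths of the external inputs (Cad, Tll).
  E:
    Hb:  {Cad: 0.0,  Tll: 0.08}
    Kr:  {Cad: 0.0,  Tll: -0.1}
    Gt:  {Cad: 0.05, Tll: -0.04}
    Kni: {Cad: 0.06, Tll: -0.3}
  h: {Hb: -2.6, Kr: -0.8, Gt: -1.4, Kni: -2.1}        # thresholds

bcd:
  A: 351.0          # a.u.
  lambda: 0.1651    # EL

schedule:
  nc13_interphase: 16.0   # min
  mitosis: 5.0            # min (synthesis gated off)
  nc14_duration: 50.0     # min; total 71 min

# Synthetic stand-in tables for the Cad and Tll upstream inputs.
external_inputs:
  cad_amplitude: [75.0, 30.0]   # a.u., start -> end of the simulated window
  cad_midpoint: 0.62            # EL
  cad_width: 0.035              # EL
  tll_amplitude: 100.0          # a.u.
  tll_midpoint: 0.82            # EL
  tll_width: 0.03               # EL
  tll_ramp: [5.0, 35.0]         # min, amplitude ramp interval
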