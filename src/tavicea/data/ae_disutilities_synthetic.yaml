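# Adverse-event disutilities for the scenario analysis - SYNTHETIC except
# the stroke value.  The stroke decrement (0.161, applied per cycle while
# in the stroke state) is the published value; the one-off decrements for
# the transient AEs come from a supplementary table that is not part of
# this package's sources and are replaced by a uniform stand-in: a 0.1
# utility loss lasting one month, i.e. a one-off QALY loss of 0.1/12.
stroke_per_cycle: 0.161
one_off:
  rehospitalisation: 0.00833
  mi: 0.00833
  major_vascular: 0.00833
  bleeding: 0.00833
  endocarditis: 0.00833
  aki: 0.00833
  new_ppi: 0.00833
  tia: 0.00833
  af: 0.00833
  par: 0.00833
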