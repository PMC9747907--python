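name,dimension,rr_outcome,p_outcome,unit_cost,currency_year,include_in_total,countable,iq_points_per_ptb
neonatal_death,health,5.0,0.003,0.0,2015,False,True,0.0
child_asthma,health,1.15,0.06,0.0232,2015,True,True,0.0
t1d,health,1.18,0.0002,0.2,2014,True,True,0.0
t2d,health,1.49,0.09,0.048567,2014,True,True,0.0
reduced_iq,cognition,1.0,0.01,0.011298,2015,True,False,8.4
asd,non-cognition,1.7,0.009,1.805936,2015,True,True,0.0
adhd,non-cognition,1.6,0.05,0.182119,2015,True,True,0.0
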