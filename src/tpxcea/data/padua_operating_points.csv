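# Padua risk assessment model operating points (fractions).
# Greene2016: exclusively medical inpatient cohort; Elias2017: mixed
# medical/surgical cohort (used in the high-performance scenario analysis).
ram,cohort,threshold,sensitivity,specificity
Padua,Greene2016,1,0.92,0.17
Padua,Greene2016,2,0.69,0.49
Padua,Greene2016,3,0.493,0.730
Padua,Greene2016,4,0.37,0.84
Padua,Greene2016,5,0.19,0.91
Padua,Greene2016,6,0.10,0.96
Padua,Greene2016,7,0.05,0.98
Padua,Elias2017,1,1.00,0.11
Padua,Elias2017,2,1.00,0.20
Padua,Elias2017,3,0.999,0.237
Padua,Elias2017,4,0.96,0.41
Padua,Elias2017,5,0.85,0.57
Padua,Elias2017,6,0.77,0.72
Padua,Elias2017,7,0.56,0.87
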