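schema: greenwallcba/params-v1
# Consumer price index on the EU27 scale (2002 = 93.58, 2010 = 111.91,
# 2011 = 115.38).  Entries for 1999/2000/2003 are back-derived from the
# published update factors to 2010 (1.25, 1.22, 1.15) so that index ratios
# reproduce those factors.
cpi:
  1999: 89.528
  2000: 91.72951
  2002: 93.58
  2003: 97.31304
  2010: 111.91
  2011: 115.38
# EUR per unit of local currency, keyed by currency and data year.
fx:
  CAD:
    1999: 0.6313
    2010: 0.7325
  JPY:
    1999: 0.0082
    2003: 0.0076
  USD:
    2000: 1.0827
  EUR:
    2010: 1.0
    2011: 1.0
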