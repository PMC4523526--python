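source_currency,source_year,target_currency,target_year,factor,provenance
CHF,1996,GBP,2012,4.214027,derived: calibrated from the printed Hertel pair (24824 CHF -> 104609 GBP)
CHF,1996,GBP,1996,2.617961,synthetic reconstruction: Hertel composite divided by the 1996->2012 inflation step below; not a market rate
GBP,1996,GBP,2012,1.609660,reconstruction: UK CPI-style inflation step chosen so the split chain recomposes the Hertel composite
GBP,1965,GBP,2012,17.081994,derived: Dundee lifetime cost pair (9952 GBP 1965 -> 0.17M GBP 2012)
USD,2009,GBP,2012,0.593407,derived: Chung first-two-years pair (45500 USD -> 27000 GBP annual equivalent)
GBP,2012,USD,2012,1.541667,derived: headline pair (288M GBP -> 444M USD)
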