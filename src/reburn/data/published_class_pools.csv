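fri_class,component,postfire_reference_pool,prefire_pool,loss,interval_years
long,belowground,5083,8240,3157,102
mid,belowground,5083,6039,2689,45
short,belowground,5083,4566,2525,16
triple_mid,belowground,3350,6260,2149,39
triple_short,belowground,3350,5822,2553,21
long,aboveground,1501,1919,418,102
mid,aboveground,1501,1931,554,45
short,aboveground,1501,1873,652,16
triple_mid,aboveground,1377,901,357,39
triple_short,aboveground,1377,720,186,21
long,total,6584,10159,3575,102
mid,total,6584,7970,3243,45
short,total,6584,6440,3177,16
triple_mid,total,4727,7161,2506,39
triple_short,total,4727,6543,2739,21
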