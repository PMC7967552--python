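year,income_index,price_index
2007,92.4,80.4
2008,103.9,90.6
2009,116.8,98.9
2010,100.0,100.0
2011,88.1,98.9
2012,97.1,101.3
2013,106.4,102.5
2014,112.3,104.1
2015,123.7,105.0
2016,133.0,107.3
2017,138.6,119.9
2018,149.1,122.4
2019,160.3,124.9
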