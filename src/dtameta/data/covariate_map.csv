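author,year,background_table_row,note
Adubeio,2018,1,
Barral,2015,2,
Wang,2017,3,"Wang with 67 patients, Philips; targeted biopsy"
Li,2015,4,
Koo,2013,5,
Feng,2017,6,"three b-value arms (2000/3200/4500) share one covariate row"
Kim,2010,7,
Wang,2015,8,"Wang with 80 patients, GE; prostatectomy"
Zhang,2016,9,"Zhang with 40 patients; two arms (2000/3000)"
Peng,2013,10,
Meng,2017,11,"population recorded as suspected (urinary symptoms, no confirmed PCa)"
Zhang,2017,12,"Zhang with 170 patients; three arms (2000/2500/3000)"
Ning,2018,13,
Wang,2016,14,"Wang with 60 patients, Siemens; population suspected (elevated PSA)"
Xue,2017,15,
Costa,2016,16,"MRI supplier not reported"
Katahira,2011,17,
Ohgiya,2012,18,
Rosenkrantz,2015,19,
Stanzione,2016,20,
Thestrup,2016,21,
Ueno1,2013,22,
Ueno2,2013,23,
Ueno,2015,24,
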