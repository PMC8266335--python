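study_id,author,year,b_value,tp,fp,fn,tn,design,n_patients,mean_age,field_strength,measure,supplier,population,biopsy_type,b_method
adubeio2018,Adubeio,2018,2000,40,3,3,30,prospective,43,63,3.0,visual,Philips,PCa,mixed,signal_extrapolation
barral2015,Barral,2015,2000,62,1,16,34,prospective,35,64,3.0,visual,Siemens,PCa,prostatectomy,motion_probing_gradients
wang2017,Wang,2017,2000,40,5,13,35,prospective,67,68.3,3.0,visual,Philips,PCa,targeted,motion_probing_gradients
li2015,Li,2015,2000,23,2,4,18,prospective,47,68,3.0,visual,Siemens,PCa,prostatectomy,motion_probing_gradients
koo2013,Koo,2013,2000,152,22,53,573,retrospective,80,66,3.0,visual,Philips,PCa,prostatectomy,motion_probing_gradients
feng2017_b2000,Feng,2017,2000,136,51,2,147,prospective,56,66.71,3.0,ADC,GE,PCa,targeted,signal_extrapolation
feng2017_b3200,Feng,2017,3200,124,28,14,170,prospective,56,66.71,3.0,ADC,GE,PCa,targeted,signal_extrapolation
feng2017_b4500,Feng,2017,4500,117,15,21,183,prospective,56,66.71,3.0,ADC,GE,PCa,targeted,signal_extrapolation
kim2010,Kim,2010,2000,128,40,52,452,retrospective,48,66,3.0,visual,Philips,PCa,prostatectomy,signal_extrapolation
wang2015,Wang,2015,2000,81,12,29,292,prospective,80,66,3.0,visual,GE,PCa,prostatectomy,motion_probing_gradients
zhang2016_b2000,Zhang,2016,2000,19,5,3,13,prospective,40,67,3.0,visual,GE,PCa,systematic,signal_extrapolation
zhang2016_b3000,Zhang,2016,3000,20,3,2,15,prospective,40,67,3.0,visual,GE,PCa,systematic,signal_extrapolation
peng2013,Peng,2013,2000,49,6,12,37,retrospective,48,62.5,1.5,ADC,Philips,PCa,prostatectomy,signal_extrapolation
meng2017,Meng,2017,2000,38,3,5,34,prospective,80,72.45,3.0,ADC,GE,suspected,systematic,motion_probing_gradients
zhang2017_b2000,Zhang,2017,2000,124,7,19,20,retrospective,170,59.5,1.5,visual,GE,PCa,systematic,motion_probing_gradients
zhang2017_b2500,Zhang,2017,2500,133,6,10,21,retrospective,170,59.5,1.5,visual,GE,PCa,systematic,motion_probing_gradients
zhang2017_b3000,Zhang,2017,3000,118,7,25,20,retrospective,170,59.5,1.5,visual,GE,PCa,systematic,motion_probing_gradients
ning2018,Ning,2018,2000,50,6,11,71,retrospective,97,64,3.0,visual,GE,PCa,targeted,motion_probing_gradients
wang2016,Wang,2016,2000,32,2,4,22,prospective,60,85.5,3.0,visual,Siemens,suspected,systematic,motion_probing_gradients
xue2017,Xue,2017,2000,19,2,8,23,prospective,37,62,3.0,ADC,Philips,PCa,systematic,motion_probing_gradients
costa2016,Costa,2016,2000,20,19,6,73,prospective,49,61,3.0,visual,,PCa,prostatectomy,both
katahira2011,Katahira,2011,2000,1162,332,425,2896,retrospective,201,69,1.5,visual,Philips,PCa,prostatectomy,motion_probing_gradients
ohgiya2012,Ohgiya,2012,2000,42,2,13,16,retrospective,73,70,3.0,visual,Siemens,PCa,prostatectomy,motion_probing_gradients
rosenkrantz2015,Rosenkrantz,2015,2000,46,10,16,564,retrospective,106,62,3.0,visual,Siemens,PCa,prostatectomy,motion_probing_gradients
stanzione2016,Stanzione,2016,2000,29,1,5,52,prospective,82,65,3.0,visual,Siemens,PCa,prostatectomy,motion_probing_gradients
thestrup2016,Thestrup,2016,2000,65,116,3,20,retrospective,204,64.1,3.0,visual,Philips,PCa,prostatectomy,motion_probing_gradients
ueno1_2013,Ueno1,2013,2000,276,79,65,164,retrospective,73,67,3.0,visual,Philips,PCa,prostatectomy,motion_probing_gradients
ueno2_2013,Ueno2,2013,2000,272,95,55,218,retrospective,80,67,3.0,visual,Philips,PCa,prostatectomy,motion_probing_gradients
ueno2015,Ueno,2015,2000,86,51,35,76,retrospective,31,65,3.0,visual,Philips,PCa,prostatectomy,motion_probing_gradients
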