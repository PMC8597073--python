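symptom,observed,orientation
Protein losing enteropathy,yes,bad
Preserved ventricular function,yes,bad
Exercise tolerance >= level X,yes,good
Central venous pressure >= level Y,no,good
Number of prior surgeries >= Z,yes,bad
Severe liver cirrhosis,no,good
Kidney function: creatinine >= level A,yes,bad
Healthy body mass index,yes,good
Support network,yes,good
High antibodies (= long wait expected),yes,bad
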