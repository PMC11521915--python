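specialty,cost_per_admission_inr
Paediatrics,10415
General Medicine,10481
Obstetrics and gynaecology,13286
Ear Nose and Throat,14104
General Surgery,13011
Ophthalmology,9867
Orthopedics,13925
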