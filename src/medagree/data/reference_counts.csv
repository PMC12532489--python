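medication_id,display_name,med_class,prescription_only,tn,fn,fp,tp,excluded,kappa,kappa_lo,kappa_hi,sensitivity,sensitivity_lo,sensitivity_hi,ppv,ppv_lo,ppv_hi,npv,npv_lo,npv_hi,optimal_window_months
azathioprine,Azathioprine,csDMARD,yes,23560,18,43,129,243,0.81,0.76,0.86,0.88,0.81,0.93,0.75,0.68,0.81,1,1,1,3
cyclosporin,Cyclosporin,csDMARD,yes,23651,13,15,73,241,0.84,0.78,0.9,0.85,0.76,0.92,0.83,0.73,0.9,1,1,1,3
gold_im,Gold (intramuscular),csDMARD,yes,23802,11,14,25,141,0.67,0.54,0.8,0.69,0.52,0.84,0.64,0.47,0.79,1,1,1,6
hydroxychloroquine,Hydroxychloroquine,csDMARD,yes,20097,385,412,2888,211,0.86,0.85,0.87,0.88,0.87,0.89,0.88,0.86,0.89,0.98,0.98,0.98,6
leflunomide,Leflunomide,csDMARD,yes,20734,311,402,2330,216,0.85,0.84,0.86,0.88,0.87,0.89,0.85,0.84,0.87,0.99,0.98,0.99,3
methotrexate_inj,Methotrexate (injection),csDMARD,yes,22600,166,241,815,171,0.79,0.77,0.81,0.83,0.81,0.85,0.77,0.75,0.8,0.99,0.99,0.99,6
methotrexate_oral,Methotrexate (oral),csDMARD,yes,10615,1174,1343,10759,102,0.79,0.78,0.8,0.9,0.9,0.91,0.89,0.88,0.89,0.9,0.89,0.91,12
penicillamine,Penicillamine,csDMARD,yes,23680,1,6,18,288,0.84,0.72,0.96,0.95,0.74,1,0.75,0.53,0.9,1,1,1,12
sulfasalazine,Sulfasalazine,csDMARD,yes,21233,328,292,1906,234,0.85,0.83,0.86,0.85,0.84,0.87,0.87,0.85,0.88,0.98,0.98,0.99,6
abatacept_infusion,Abatacept (infusion),btsDMARD,yes,23472,33,91,367,30,0.85,0.83,0.88,0.92,0.89,0.94,0.8,0.76,0.84,1,1,1,3
abatacept_inj,Abatacept (injection),btsDMARD,yes,23052,154,79,706,2,0.85,0.83,0.87,0.82,0.79,0.85,0.9,0.88,0.92,0.99,0.99,0.99,3
adalimumab,Adalimumab,btsDMARD,yes,18100,423,277,5119,74,0.92,0.91,0.92,0.92,0.92,0.93,0.95,0.94,0.95,0.98,0.97,0.98,3
certolizumab,Certolizumab pegol,btsDMARD,yes,23322,78,45,541,7,0.9,0.88,0.91,0.87,0.85,0.9,0.92,0.9,0.94,1,1,1,3
etanercept,Etanercept,btsDMARD,yes,18482,365,221,4890,35,0.93,0.92,0.93,0.93,0.92,0.94,0.96,0.95,0.96,0.98,0.98,0.98,3
golimumab,Golimumab,btsDMARD,yes,22342,145,105,1397,4,0.91,0.9,0.92,0.91,0.89,0.92,0.93,0.92,0.94,0.99,0.99,0.99,3
infliximab,Infliximab,btsDMARD,yes,23112,31,41,700,109,0.95,0.94,0.96,0.96,0.94,0.97,0.94,0.93,0.96,1,1,1,6
rituximab,Rituximab,btsDMARD,yes,23172,68,327,354,72,0.63,0.6,0.67,0.84,0.8,0.87,0.52,0.48,0.56,1,1,1,12
tocilizumab,Tocilizumab,btsDMARD,yes,22544,153,106,1175,15,0.9,0.88,0.91,0.88,0.87,0.9,0.92,0.9,0.93,0.99,0.99,0.99,3
tofacitinib,Tofacitinib citrate,btsDMARD,yes,23232,103,88,562,8,0.85,0.83,0.87,0.85,0.82,0.87,0.86,0.84,0.89,1,0.99,1,3
ustekinumab,Ustekinumab,btsDMARD,yes,23900,10,15,63,5,0.83,0.77,0.9,0.86,0.76,0.93,0.81,0.7,0.89,1,1,1,6
morphine,Morphine,opioid_analgesic,yes,23684,34,177,98,0,0.48,0.41,0.55,0.74,0.66,0.81,0.36,0.3,0.42,1,1,1,3
oxycodone,Oxycodone,opioid_analgesic,yes,21987,650,507,849,0,0.57,0.54,0.59,0.57,0.54,0.59,0.63,0.6,0.65,0.97,0.97,0.97,3
paracetamol_codeine,Paracetamol and codeine,opioid_analgesic,no,19049,1159,2134,1651,0,0.42,0.4,0.44,0.59,0.57,0.61,0.44,0.42,0.45,0.94,0.94,0.95,6
tramadol,Tramadol,opioid_analgesic,yes,22517,293,368,815,0,0.7,0.67,0.72,0.74,0.71,0.76,0.69,0.66,0.72,0.99,0.99,0.99,3
aspirin,Aspirin,nonopioid_analgesic,no,21350,392,1843,408,0,0.23,0.2,0.26,0.51,0.47,0.55,0.18,0.17,0.2,0.98,0.98,0.98,12
celecoxib,Celecoxib,nonopioid_analgesic,yes,21520,285,647,1541,0,0.75,0.73,0.76,0.84,0.83,0.86,0.7,0.68,0.72,0.99,0.99,0.99,3
diclofenac,Diclofenac,nonopioid_analgesic,no,22819,220,354,600,0,0.66,0.64,0.69,0.73,0.7,0.76,0.63,0.6,0.66,0.99,0.99,0.99,6
ibuprofen,Ibuprofen,nonopioid_analgesic,no,21259,254,2123,357,0,0.2,0.17,0.23,0.58,0.54,0.62,0.14,0.13,0.16,0.99,0.99,0.99,12
indometacin,Indometacin,nonopioid_analgesic,yes,23617,101,88,187,0,0.66,0.61,0.71,0.65,0.59,0.7,0.68,0.62,0.73,1,0.99,1,6
ketoprofen,Ketoprofen,nonopioid_analgesic,yes,23684,29,74,206,0,0.8,0.76,0.84,0.88,0.83,0.92,0.74,0.68,0.79,1,1,1,3
meloxicam,Meloxicam,nonopioid_analgesic,yes,21186,628,507,1672,0,0.72,0.7,0.74,0.73,0.71,0.75,0.77,0.75,0.78,0.97,0.97,0.97,6
naproxen,Naproxen,nonopioid_analgesic,no,22312,309,340,1032,0,0.75,0.73,0.77,0.77,0.75,0.79,0.75,0.73,0.77,0.99,0.98,0.99,6
paracetamol,Paracetamol,nonopioid_analgesic,no,12382,1144,8178,2289,0,0.15,0.13,0.16,0.67,0.65,0.68,0.22,0.21,0.23,0.92,0.91,0.92,12
piroxicam,Piroxicam,nonopioid_analgesic,yes,23665,78,58,192,0,0.74,0.69,0.78,0.71,0.65,0.76,0.77,0.71,0.82,1,1,1,12
prednisolone,Prednisolone/prednisone,glucocorticoid,yes,16288,1265,1445,4856,139,0.71,0.69,0.72,0.79,0.78,0.8,0.77,0.76,0.78,0.93,0.92,0.93,3
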