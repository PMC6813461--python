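Patients,Age range (years),Current treatments,Disease duration (months),DAS28,Anti-CCP,Erosion,RF
PAT-1,36-40,Prednisone,28,2.70,Yes,Yes,Yes
PAT-2,80-85,Tocilizumab,172,6.85,Yes,Yes,Yes
PAT-3,40-45,Nonsteroidal anti-inflammatory drugs,124,5.49,Yes,Yes,Yes
PAT-4,71-75,Tocilizumab,76,3.49,Yes,Yes,No
PAT-5,81-85,"Etanercept, Methotrexate",136,2.68,Yes,Yes,NA
PAT-6,56-60,Methotrexate,76,1.89,NA,NA,NA
PAT-7,56-60,"Methotrexate, Hydroxychloroquine, Salazopyrine, Prednisone",148,2.58,Yes,No,Yes
PAT-8,50-55,"Rituximab, Methotrexate",244,2.97,Yes,Yes,Yes
PAT-9,56-70,"Rituximab, Methotrexate",304,2.56,Yes,Yes,Yes
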