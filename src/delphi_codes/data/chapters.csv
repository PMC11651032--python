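chapter_id,name,prefix_start,prefix_end,family
infectious_parasitic,Infectious and Parasitic Diseases,001,139,numeric
neoplasms,Neoplasms,140,239,numeric
endocrine_metabolic,"Endocrine, Nutritional and Metabolic Diseases, and Immunity Disorders",240,279,numeric
blood,Diseases of the Blood and Blood-Forming Organs,280,289,numeric
mental,Mental Disorders,290,319,numeric
nervous_sense,Diseases of the Nervous System and Sense Organs,320,389,numeric
circulatory,Diseases of the Circulatory System,390,459,numeric
respiratory,Diseases of the Respiratory System,460,519,numeric
digestive,Diseases of the Digestive System,520,579,numeric
genitourinary,Diseases of the Genitourinary System,580,629,numeric
pregnancy,"Complications of Pregnancy, Childbirth, and the Puerperium",630,679,numeric
skin,Diseases of the Skin and Subcutaneous Tissue,680,709,numeric
musculoskeletal,Diseases of the Musculoskeletal System and Connective Tissue,710,739,numeric
congenital,Congenital Anomalies,740,759,numeric
perinatal,Certain Conditions Originating in the Perinatal Period,760,779,numeric
symptoms_illdefined,"Symptoms, Signs, and Ill-Defined Conditions",780,799,numeric
injury_poisoning,Injury and Poisoning,800,999,numeric
supplementary_v,Supplementary Classification of Factors Influencing Health Status and Contact with Health Services,V00,V99,V
supplementary_e,Supplementary Classification of External Causes of Injury and Poisoning,E000,E999,E
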