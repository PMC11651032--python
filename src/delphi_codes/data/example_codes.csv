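code,description,is_covid
003.0,Salmonella gastroenteritis,0
008.45,Intestinal infection due to Clostridium difficile,0
009.0,Infectious colitis enteritis and gastroenteritis,0
011.93,Pulmonary tuberculosis unspecified,0
038.9,Unspecified septicemia,0
041.7,Pseudomonas infection in conditions classified elsewhere,0
070.54,Chronic hepatitis C without mention of hepatic coma,0
079.99,Unspecified viral infection,0
112.0,Candidiasis of mouth,0
136.9,Unspecified infectious and parasitic disease,0
162.9,Malignant neoplasm of bronchus and lung unspecified,0
250.00,Diabetes mellitus without mention of complication type II,0
285.9,Anemia unspecified,0
290.0,Senile dementia uncomplicated,0
320.9,Meningitis due to unspecified bacterium,0
345.90,Epilepsy unspecified,0
410.90,Acute myocardial infarction unspecified site,0
428.0,Congestive heart failure unspecified,0
466.0,Acute bronchitis,0
481,Pneumococcal pneumonia,0
486,Pneumonia organism unspecified,0
491.21,Obstructive chronic bronchitis with acute exacerbation,0
540.9,Acute appendicitis without mention of peritonitis,0
567.9,Unspecified peritonitis,0
574.00,Calculus of gallbladder with acute cholecystitis,0
590.10,Acute pyelonephritis without lesion of renal medullary necrosis,0
599.0,Urinary tract infection site not specified,0
646.60,Infections of genitourinary tract in pregnancy unspecified,0
680.9,Carbuncle and furuncle of unspecified site,0
682.6,Cellulitis and abscess of leg except foot,0
707.14,Ulcer of heel and midfoot,0
711.00,Pyogenic arthritis site unspecified,0
730.20,Unspecified osteomyelitis site unspecified,0
771.81,Septicemia of newborn,0
780.60,Fever unspecified,0
790.7,Bacteremia,0
883.0,Open wound of finger without mention of complication,0
941.20,Burn of blisters epidermal loss of face and head unspecified site,0
958.3,Posttraumatic wound infection not elsewhere classified,0
998.59,Other postoperative infection,0
V09.0,Infection with microorganisms resistant to penicillins,0
V58.62,Long-term current use of antibiotics,0
E878.8,Other specified surgical operations as the cause of abnormal reaction,0
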