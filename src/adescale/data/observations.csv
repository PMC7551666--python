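drug_name,drug_class,series,indication,route,adult_clearance,clearance_units,age_label,maturity,observed_clearance,paper_predicted_clearance,paper_percent_error,weight_kg,exponent_override
Basiliximab,monoclonal,,Liver Transplantation,IV,55,mL/h,<2,not_applicable,19,8,-59,,
Basiliximab,monoclonal,,Liver Transplantation,IV,55,mL/h,3.5,not_applicable,24,18,-26,,
Basiliximab,monoclonal,,Liver Transplantation,IV,55,mL/h,8.6,not_applicable,28,33,17,,
Basiliximab,monoclonal,,Liver Transplantation,IV,55,mL/h,13.5,not_applicable,49,43,-13,,
Basiliximab,monoclonal,,Renal Transplantation,IV,37,mL/h,1–4 y,not_applicable,15,15,-2,,
Basiliximab,monoclonal,,Renal Transplantation,IV,37,mL/h,6–12 y,not_applicable,19,24,28,,
Basiliximab,monoclonal,,Renal Transplantation,IV,37,mL/h,14–16 y,not_applicable,30,31,3,,
Cetuximab,monoclonal,,Solid Tumors,IV,46,mL/h,1–12 y,not_applicable,18,24,35,,
Cetuximab,monoclonal,,Solid Tumors,IV,46,mL/h,13–18 y,not_applicable,32,38,20,,
Gemtuzumab,monoclonal,,Refractory or Relapsed Acute Myeloid Leukemia,IV,270,mL/h,1–5 y,not_applicable,120,87,-27,,
Gemtuzumab,monoclonal,,Refractory or Relapsed Acute Myeloid Leukemia,IV,270,mL/h,>5–12 y,not_applicable,180,161,-11,,
Gemtuzumab,monoclonal,,Refractory or Relapsed Acute Myeloid Leukemia,IV,270,mL/h,>12–16 y,not_applicable,230,225,-2,,
Infliximab,monoclonal,,Kawasaki Disease,IV,9.5,mL/h,0.7–3.1 y,not_applicable,1.7,2.0,20,,
Infliximab,monoclonal,,Kawasaki Disease,IV,9.5,mL/h,0.2–6.25 y,not_applicable,3.0,2.7,-10,,
Natalizumab,monoclonal,,Crohn Disease,IV,22,mL/h,11–17 y,not_applicable,18,20,12,,
Canakinumab,monoclonal,,Systemic Juvenile Idiopathic Arthritis,SC,9,mL/h,0.7–1.7 y,not_applicable,1.8,1.3,-27,,
Canakinumab,monoclonal,,Systemic Juvenile Idiopathic Arthritis,SC,9,mL/h,2.7–4.9 y,not_applicable,4.6,3.2,-30,,
Canakinumab,monoclonal,,Systemic Juvenile Idiopathic Arthritis,SC,9,mL/h,5.9–11.1 y,not_applicable,7.2,5.9,-17,,
Canakinumab,monoclonal,,Systemic Juvenile Idiopathic Arthritis,SC,9,mL/h,12–17.2 y,not_applicable,8.3,7.5,-9,,
Canakinumab,monoclonal,,Cryopyrin-Associated Periodic Syndrome,SC,9.5,mL/h,age not known (youngest may be 4 years),not_applicable,2.4,2.7,9,17.3,0.9
Canakinumab,monoclonal,,Cryopyrin-Associated Periodic Syndrome,SC,9.5,mL/h,age not known (youngest may be 4 years),not_applicable,5.4,5.1,-6,30.5,0.75
Canakinumab,monoclonal,,Cryopyrin-Associated Periodic Syndrome,SC,9.5,mL/h,age not known (youngest may be 4 years),not_applicable,9.7,6.9,-29,45.7,0.75
Urtoxazumab,monoclonal,,Shiga-Like Toxin (Escherichia coli),IV,6,mL/h,2.9,not_applicable,1.8,1.9,3,,
Tocilizumab,monoclonal,,Polyarticular Juvenile Idiopathic Arthritis,IV,20.3,mL/h,"20 kg, age not known",not_applicable,8.6,7.9,-8,20,0.75
Daclizumab,monoclonal,,Renal Transplant,IV,13,mL/h,<5 y,not_applicable,5.2,3.2,-38,,
Daclizumab,monoclonal,,Renal Transplant,IV,13,mL/h,6–12 y,not_applicable,10.8,6.9,-36,,
Daclizumab,monoclonal,,Renal Transplant,IV,13,mL/h,13–17 y,not_applicable,14.5,10.4,-28,,
Belacept,monoclonal,,Kidney Transplant,IV,36,mL/h,13–17 y,not_applicable,28,32,12,,
MEDI8897,monoclonal,,Respiratory Syncytial Virus Prophylaxis,IM,65,mL/day,4.2 months,not_applicable,4.1,5.3,30,,
MEDI8897,monoclonal,,Respiratory Syncytial Virus Prophylaxis,IM,65,mL/day,6.7 months,not_applicable,6.1,6.3,4,,
MEDI8897,monoclonal,,Respiratory Syncytial Virus Prophylaxis,IM,65,mL/day,7 months,not_applicable,7.0,6.6,-6,,
Bevacizumab,monoclonal,,CNS Malignancies,IV,9.8,mL/h,11–31 months,not_applicable,2.8,2.6,-7,,
Palivizumab,monoclonal,,Respiratory Syncytial Virus,IM,198,mL/day,12.3 months,not_applicable,11.0,12.7,15,,
Panzyga,polyclonal,baseline uncorrected,Immunodeficiency,IV,101,mL/day,2–5.9,not_applicable,48,39,-18,,
Panzyga,polyclonal,baseline uncorrected,Immunodeficiency,IV,101,mL/day,6–11.9,not_applicable,50,48,-4,,
Panzyga,polyclonal,baseline uncorrected,Immunodeficiency,IV,101,mL/day,12–16,not_applicable,82,78,-4,,
Panzyga,polyclonal,baseline corrected,Immunodeficiency,IV,504,mL/day,2–5.9,not_applicable,192,197,3,,
Panzyga,polyclonal,baseline corrected,Immunodeficiency,IV,504,mL/day,6–11.9,not_applicable,200,240,20,,
Panzyga,polyclonal,baseline corrected,Immunodeficiency,IV,504,mL/day,12–16,not_applicable,504,392,-22,,
Gammaplex 10%,polyclonal,baseline corrected,Immunodeficiency,IV,456,mL/day,2–5,not_applicable,114,114,0,,
Gammaplex 10%,polyclonal,baseline corrected,Immunodeficiency,IV,456,mL/day,6–11,not_applicable,178,181,1,,
Gammaplex 10%,polyclonal,baseline corrected,Immunodeficiency,IV,456,mL/day,12–15,not_applicable,381,367,-4,,
GAMUNEX-C,polyclonal,baseline uncorrected,Immunodeficiency,IV,101,mL/day,2–5,not_applicable,20,26,31,,
GAMUNEX-C,polyclonal,baseline uncorrected,Immunodeficiency,IV,101,mL/day,6–11,not_applicable,44,41,-6,,
GAMUNEX-C,polyclonal,baseline uncorrected,Immunodeficiency,IV,101,mL/day,12–16,not_applicable,84,82,-3,,
Cuvitru,polyclonal,baseline uncorrected,Immunodeficiency,SC,150,mL/day,2–<5,not_applicable,37,37,1,,
Cuvitru,polyclonal,baseline uncorrected,Immunodeficiency,SC,150,mL/day,5–<12,not_applicable,48,59,22,,
Cuvitru,polyclonal,baseline uncorrected,Immunodeficiency,SC,150,mL/day,12–16 y,not_applicable,103,117,14,,
Hizentra,polyclonal,baseline uncorrected,Immunodeficiency,SC,161,mL/day,6–<12 y,not_applicable,55,74,35,,
Hizentra,polyclonal,baseline uncorrected,Immunodeficiency,SC,161,mL/day,12–<16 y,not_applicable,119,134,13,,
Sandoglobulin,polyclonal,baseline uncorrected,Immunodeficiency,IV,110,mL/day,Preterm,preterm,4.2,2.1,-50,,
Gamimune,polyclonal,baseline uncorrected,Immunodeficiency,IV,110,mL/day,250 (term),term,2.8,3.1,10,,
Gamimune,polyclonal,baseline uncorrected,Immunodeficiency,IV,110,mL/day,500 (term),term,4.1,3.3,-18,,
Gamimune,polyclonal,baseline uncorrected,Immunodeficiency,IV,110,mL/day,1000 (preterm),preterm,3.6,1.9,-47,,
Bivalirudin,non_antibody,,Percutaneous Coronary Intervention,IV,238,mL/min,<30 days,term,40,9,-77,,
Bivalirudin,non_antibody,,Percutaneous Coronary Intervention,IV,238,mL/min,31 days <2,not_applicable,83,28,-66,,
Bivalirudin,non_antibody,,Percutaneous Coronary Intervention,IV,238,mL/min,2–<6,not_applicable,137,86,-37,,
Bivalirudin,non_antibody,,Percutaneous Coronary Intervention,IV,238,mL/min,6–<16,not_applicable,245,159,-35,,
Darbepoetin alfa,non_antibody,,Chronic Kidney Disease,IV,112,mL/h,1–17,not_applicable,81,67,-17,,
Darbepoetin alfa,non_antibody,,Chronic Kidney Disease,IV,112,mL/h,<12,not_applicable,55,45,-19,,
Darbepoetin alfa,non_antibody,,Chronic Kidney Disease,IV,112,mL/h,>12,not_applicable,49,64,30,,
Erythropoietin,non_antibody,,End Stage Renal Failure,IV,361,mL/h,9–12,not_applicable,263,177,-33,,
Erythropoietin,non_antibody,,End Stage Renal Failure,IV,361,mL/h,>12–16,not_applicable,429,242,-44,,
Interleukin 11,non_antibody,,Solid Tumors or Lymphoma,IV,26,L/h,>1–3,not_applicable,4.9,4.1,-17,,
Interleukin 11,non_antibody,,Solid Tumors or Lymphoma,IV,26,L/h,>3–<13,not_applicable,13.2,12.5,-5,,
Interleukin 11,non_antibody,,Solid Tumors or Lymphoma,IV,26,L/h,>13–<17,not_applicable,23.8,20.4,-14,,
Drotrecogin alfa (activated),non_antibody,,Chronic Kidney Disease,IV,38,L/h,<1 year,not_applicable,3.4,3.3,-4,,
Drotrecogin alfa (activated),non_antibody,,Chronic Kidney Disease,IV,38,L/h,1–8 year,not_applicable,12,18,46,,
Glulisine,non_antibody,,Type 1 Diabetes,SC,53,mL/h,5–11 year,not_applicable,45,35,-23,,
Glulisine,non_antibody,,Type 1 Diabetes,SC,53,mL/h,11–17 year,not_applicable,65,50,-24,,
Regular Human Insulin,non_antibody,,Type 1 Diabetes,SC,55,mL/h,5–11 year,not_applicable,65,36,-44,,
Regular Human Insulin,non_antibody,,Type 1 Diabetes,SC,55,mL/h,11–17 year,not_applicable,63,51,-18,,
Growth Hormone (LB03002),non_antibody,,Growth Hormone Deficiency,SC,25,L/h,7 years,not_applicable,9.1,11.5,27,,
Enfuvirtide,non_antibody,,HIV-1 Infection,SC,1310,mL/h,>5–<12 year,not_applicable,666,640,-3,,
Enfuvirtide,non_antibody,,HIV-1 Infection,SC,1310,mL/h,>12–<17 year,not_applicable,970,960,-1,,
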