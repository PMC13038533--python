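soc,pt,cases,ror,ror_l95,ror_u95,deaths,event_status,evidence,printed_score,printed_tier
Eye disorders,Choroiditis,47,92.85,69.26,124.49,0,IME,-,4,weak
Eye disorders,Visual acuity reduced,54,60.02,45.74,78.75,0,none,++,6,moderate
Eye disorders,Mydriasis,40,59.34,43.34,81.25,0,none,++,5,moderate
Eye disorders,Uveitis,47,57.41,42.93,76.76,0,IME,-,4,weak
Eye disorders,Eye pain,64,42.27,32.9,54.29,0,none,++,6,moderate
Eye disorders,Choroidal detachment,10,20.72,11.1,38.67,0,IME,-,4,weak
Eye disorders,Corneal oedema,7,14.18,6.75,29.82,0,none,+,3,weak
Eye disorders,Photophobia,10,11.43,6.14,21.28,0,none,++,5,moderate
Eye disorders,Vision blurred,22,8.64,5.67,13.16,0,none,++,5,moderate
Eye disorders,Visual impairment,19,6.41,4.08,10.08,0,none,++,5,moderate
Eye disorders,Eye irritation,9,8.17,4.24,15.73,0,none,++,4,weak
Eye disorders,Eye discharge,6,9.79,4.39,21.82,0,none,+,3,weak
Eye disorders,Iridocyclitis,5,10.11,4.2,24.33,0,IME,-,3,weak
Eye disorders,Ulcerative keratitis,5,10.1,4.2,24.3,0,IME,-,3,weak
Eye disorders,Strabismus,5,9.96,4.14,23.96,0,none,+,3,weak
Eye disorders,Posterior capsule opacification,4,8.86,3.32,23.67,0,IME,-,3,weak
Eye disorders,Retinal detachment,4,6.98,2.62,18.62,0,IME,++,5,moderate
Eye disorders,Eye pruritus,5,5.33,2.22,12.84,0,none,+,3,weak
Eye disorders,Anterior segment ischemia,3,6.99,2.23,21.92,0,IME,-,3,weak
Eye disorders,Ciliary hyperemia,3,6.98,2.23,21.83,0,none,-,2,weak
Eye disorders,Lagophthalmos,3,6.92,2.22,21.49,0,none,-,2,weak
Eye disorders,Corneal scar,3,6.88,2.21,21.37,0,none,-,2,weak
Eye disorders,Ocular hyperemia,5,4.73,1.97,11.39,0,none,++,3,weak
Eye disorders,Retinal degeneration,3,6.71,2.16,20.84,0,IME,-,3,weak
Eye disorders,Blindness,5,4.67,1.94,11.24,0,DME,++,5,moderate
Eye disorders,Vitreous hemorrhage,3,6.41,2.06,19.9,0,IME,-,3,weak
Eye disorders,Photopsia,3,5.86,1.89,18.18,0,none,++,4,weak
Eye disorders,Miosis,3,5.57,1.79,17.29,0,none,-,2,weak
Eye disorders,Eye swelling,3,3.33,1.07,10.32,0,none,++,3,weak
Cardiac disorders,Tachycardia,12,4.84,2.74,8.55,0,none,++,4,weak
Cardiac disorders,Bradycardia,4,2.96,1.11,7.89,0,none,-,1,weak
Gastrointestinal disorders,Large intestine perforation,8,13.36,6.67,26.77,0,IME,-,3,weak
Gastrointestinal disorders,Intestinal obstruction,8,6.87,3.43,13.76,0,IME,-,3,weak
Gastrointestinal disorders,Mouth swelling,4,7.29,2.73,19.44,0,none,-,2,weak
Gastrointestinal disorders,Impaired gastric emptying,3,4.58,1.48,14.22,0,IME,-,2,weak
Gastrointestinal disorders,Swollen tongue,4,3.67,1.37,9.78,0,none,++,3,weak
General disorders and administration site conditions,Thirst,9,11.65,6.05,22.43,0,none,++,4,weak
General disorders and administration site conditions,Condition aggravated,58,6.01,4.62,7.81,0,none,-,4,weak
General disorders and administration site conditions,Hyperthermia,4,6.88,2.58,18.35,0,none,++,4,weak
General disorders and administration site conditions,Feeling jittery,4,5.63,2.11,15.03,0,none,++,4,weak
General disorders and administration site conditions,Drug ineffective,42,1.85,1.36,2.52,0,none,-,1,weak
Infections and infestations,Endophthalmitis,74,128.78,101.89,162.75,0,IME,-,5,moderate
Infections and infestations,Hypopyon,4,8.8,3.3,23.49,0,IME,-,3,weak
Infections and infestations,Septic shock,8,5.06,2.53,10.14,0,IME,-,3,weak
Infections and infestations,Eye abscess,3,6.92,2.23,21.5,0,IME,+,4,weak
Infections and infestations,Conjunctivitis,4,5.1,1.91,13.61,0,none,++,4,weak
"Injury, poisoning and procedural complications",Product packaging confusion,13,25.87,14.97,44.69,0,none,-,3,weak
"Injury, poisoning and procedural complications",Product label confusion,7,8.61,4.1,18.09,0,none,-,2,weak
"Injury, poisoning and procedural complications",Anesthetic complication neurological,4,8.83,3.31,23.57,0,IME,-,3,weak
"Injury, poisoning and procedural complications",Product use issue,22,4.08,2.68,6.21,0,none,-,2,weak
"Injury, poisoning and procedural complications",Wrong product administered,4,7.49,2.81,19.97,0,none,-,2,weak
"Injury, poisoning and procedural complications",Product dispensing error,4,6.1,2.29,16.28,0,none,-,2,weak
"Injury, poisoning and procedural complications",Hyphema,3,6.86,2.21,21.31,0,IME,+,4,weak
"Injury, poisoning and procedural complications",Incorrect route of product administration,4,3.33,1.25,8.88,0,none,-,1,weak
"Injury, poisoning and procedural complications",Toxicity to various agents,9,2.13,1.11,4.1,2,none,++,5,moderate
Investigations,Intraocular pressure increased,50,75.49,56.93,100.09,0,none,++,5,moderate
Investigations,Blood pressure systolic decreased,9,14.96,7.77,28.82,0,none,-,2,weak
Investigations,Body temperature decreased,9,9.59,4.98,18.47,0,none,-,2,weak
Investigations,Blood pressure systolic increased,9,6.31,3.28,12.15,0,none,++,4,weak
Metabolism and nutrition disorders,Polydipsia,9,16.5,8.57,31.78,0,none,++,4,weak
Metabolism and nutrition disorders,Type 2 diabetes mellitus,9,3.06,1.59,5.9,0,IME,-,2,weak
Musculoskeletal and connective tissue disorders,Chondritis,4,8.93,3.34,23.87,0,none,-,2,weak
Nervous system disorders,Anticholinergic syndrome,21,40.31,26.19,62.05,0,IME,++,6,moderate
Nervous system disorders,Coma,10,7.92,4.25,14.76,0,IME,++,6,moderate
Nervous system disorders,Hypotonia,6,9.7,4.35,21.62,0,none,-,2,weak
Nervous system disorders,Pyramidal tract syndrome,4,8.88,3.32,23.72,0,IME,-,3,weak
Nervous system disorders,Somnolence,14,3.1,1.83,5.24,0,none,++,4,weak
Nervous system disorders,Myoclonus,3,4.77,1.54,14.8,0,none,++,3,weak
Product issues,Needle issue,9,10.85,5.63,20.9,0,none,-,2,weak
Psychiatric disorders,Agitation,11,6.73,3.72,12.18,0,none,++,5,moderate
Psychiatric disorders,"Hallucination, visual",6,7.19,3.22,16.03,0,IME,++,5,moderate
Psychiatric disorders,Confusional state,15,2.79,1.68,4.64,0,none,++,4,weak
Psychiatric disorders,Hallucination,5,2.76,1.15,6.65,0,IME,++,4,weak
Renal and urinary disorders,Polyuria,9,14.01,7.27,26.97,0,none,-,2,weak
Renal and urinary disorders,Pollakiuria,9,7.2,3.74,13.86,0,none,-,2,weak
Renal and urinary disorders,Urinary retention,4,3.65,1.37,9.75,0,IME,++,4,weak
Skin and subcutaneous tissue disorders,Erythema,14,3.11,1.84,5.26,0,none,++,4,weak
Skin and subcutaneous tissue disorders,Madarosis,4,5.62,2.1,14.98,0,none,+,3,weak
Skin and subcutaneous tissue disorders,Toxic epidermal necrolysis,4,5.02,1.88,13.38,0,DME,-,4,weak
Skin and subcutaneous tissue disorders,Hyperhidrosis,9,3.11,1.62,5.99,0,none,++,3,weak
Vascular disorders,Flushing,9,4.78,2.48,9.2,0,none,++,3,weak
Missing or unknown,Wrong drug administered,9,16.49,8.56,31.77,0,none,-,2,weak
Missing or unknown,Drug effect prolonged,3,6.9,2.22,21.46,0,none,-,2,weak
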