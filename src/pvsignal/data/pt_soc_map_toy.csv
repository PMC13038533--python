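pt,soc
Choroiditis,Eye disorders
Visual acuity reduced,Eye disorders
Mydriasis,Eye disorders
Uveitis,Eye disorders
Eye pain,Eye disorders
Choroidal detachment,Eye disorders
Corneal oedema,Eye disorders
Photophobia,Eye disorders
Vision blurred,Eye disorders
Visual impairment,Eye disorders
Eye irritation,Eye disorders
Eye discharge,Eye disorders
Iridocyclitis,Eye disorders
Ulcerative keratitis,Eye disorders
Strabismus,Eye disorders
Posterior capsule opacification,Eye disorders
Retinal detachment,Eye disorders
Eye pruritus,Eye disorders
Anterior segment ischemia,Eye disorders
Ciliary hyperemia,Eye disorders
Lagophthalmos,Eye disorders
Corneal scar,Eye disorders
Ocular hyperemia,Eye disorders
Retinal degeneration,Eye disorders
Blindness,Eye disorders
Vitreous hemorrhage,Eye disorders
Photopsia,Eye disorders
Miosis,Eye disorders
Eye swelling,Eye disorders
Tachycardia,Cardiac disorders
Bradycardia,Cardiac disorders
Large intestine perforation,Gastrointestinal disorders
Intestinal obstruction,Gastrointestinal disorders
Mouth swelling,Gastrointestinal disorders
Impaired gastric emptying,Gastrointestinal disorders
Swollen tongue,Gastrointestinal disorders
Thirst,General disorders and administration site conditions
Condition aggravated,General disorders and administration site conditions
Hyperthermia,General disorders and administration site conditions
Feeling jittery,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Endophthalmitis,Infections and infestations
Hypopyon,Infections and infestations
Septic shock,Infections and infestations
Eye abscess,Infections and infestations
Conjunctivitis,Infections and infestations
Product packaging confusion,"Injury, poisoning and procedural complications"
Product label confusion,"Injury, poisoning and procedural complications"
Anesthetic complication neurological,"Injury, poisoning and procedural complications"
Product use issue,"Injury, poisoning and procedural complications"
Wrong product administered,"Injury, poisoning and procedural complications"
Product dispensing error,"Injury, poisoning and procedural complications"
Hyphema,"Injury, poisoning and procedural complications"
Incorrect route of product administration,"Injury, poisoning and procedural complications"
Toxicity to various agents,"Injury, poisoning and procedural complications"
Intraocular pressure increased,Investigations
Blood pressure systolic decreased,Investigations
Body temperature decreased,Investigations
Blood pressure systolic increased,Investigations
Polydipsia,Metabolism and nutrition disorders
Type 2 diabetes mellitus,Metabolism and nutrition disorders
Chondritis,Musculoskeletal and connective tissue disorders
Anticholinergic syndrome,Nervous system disorders
Coma,Nervous system disorders
Hypotonia,Nervous system disorders
Pyramidal tract syndrome,Nervous system disorders
Somnolence,Nervous system disorders
Myoclonus,Nervous system disorders
Needle issue,Product issues
Agitation,Psychiatric disorders
"Hallucination, visual",Psychiatric disorders
Confusional state,Psychiatric disorders
Hallucination,Psychiatric disorders
Polyuria,Renal and urinary disorders
Pollakiuria,Renal and urinary disorders
Urinary retention,Renal and urinary disorders
Erythema,Skin and subcutaneous tissue disorders
Madarosis,Skin and subcutaneous tissue disorders
Toxic epidermal necrolysis,Skin and subcutaneous tissue disorders
Hyperhidrosis,Skin and subcutaneous tissue disorders
Flushing,Vascular disorders
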