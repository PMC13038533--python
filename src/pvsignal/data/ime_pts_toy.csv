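pt
Choroiditis
Uveitis
Choroidal detachment
Iridocyclitis
Ulcerative keratitis
Posterior capsule opacification
Retinal detachment
Anterior segment ischemia
Retinal degeneration
Vitreous hemorrhage
Large intestine perforation
Intestinal obstruction
Impaired gastric emptying
Endophthalmitis
Hypopyon
Septic shock
Eye abscess
Anesthetic complication neurological
Hyphema
Type 2 diabetes mellitus
Anticholinergic syndrome
Coma
Pyramidal tract syndrome
"Hallucination, visual"
Hallucination
Urinary retention
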