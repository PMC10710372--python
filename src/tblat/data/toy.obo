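format-version: 1.2
ontology: tblat-toy
remark: Small phenotype-style fixture used by the test suite and examples.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000005
name: Mode of inheritance
is_a: HP:0000001 ! All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0000478
name: Abnormality of the eye
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000518
name: Cataract
alt_id: HP:0007835
synonym: "Lens opacity" EXACT []
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000924
name: Abnormality of the skeletal system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001385
name: Hip dysplasia
synonym: "Dysplastic hip joints" EXACT []
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0009803
name: Short phalanx of finger
synonym: "Shortening of the finger phalanges" EXACT []
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0002652
name: Skeletal dysplasia
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0001627
name: Abnormal heart morphology
synonym: "Cardiac anomalies" EXACT []
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0012073
name: Abnormal urinary acylglycine profile
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0008243
name: Pseudohypoaldosteronism
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001942
name: Metabolic aciduria
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001945
name: Fever
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0002315
name: Headache
is_a: HP:0000118 ! Phenotypic abnormality
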