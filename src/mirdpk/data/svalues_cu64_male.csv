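,liver,spleen,kidneys,red_marrow,heart_content,bladder_content,remainder
adrenals,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
brain,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
breasts,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
gallbladder_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
lower_large_intestine_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
small_intestine_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
stomach_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
upper_large_intestine_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
heart_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.07104307428857119,0.00046450985864276225,0.001522983926562135
kidneys,0.0004283358948431469,0.00046757233995828296,0.25501570763367054,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.0004980016701369864
liver,0.04795510242499066,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.0004980016701369864
lungs,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
muscle,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
pancreas,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
red_marrow,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.03564544425778277,0.0004525462885711875,0.00046450985864276225,0.0004980016701369864
skeleton,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.008138439324000843,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
skin,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
spleen,0.0004283358948431469,0.5146268002428083,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.0004980016701369864
testes,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
thymus,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
thyroid,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
urinary_bladder_wall,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.17694082985864276,0.001522983926562135
lens_of_eyes,0.0004283358948431469,0.00046757233995828296,0.0004592417799865988,0.0004376544512735705,0.0004525462885711875,0.00046450985864276225,0.001522983926562135
total_body,0.0014649952043835615,0.0014649952043835615,0.0014649952043835615,0.0014649952043835615,0.0014649952043835615,0.0014649952043835615,0.0014649952043835615
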