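sentence	category	expected
No pathologically enlarged lymph nodes.	lymph_node	negated
There is no lymphadenopathy.	lymph_node	negated
Without evidence of a mass.	tumor	negated
Absence of mediastinal lymphadenopathy.	lymph_node	negated
No suspicious lymph nodes.	lymph_node	negated
Free of tumor.	tumor	negated
Negative for malignancy.	tumor	negated
No invasion of the chest wall.	invasion_target	negated
Neither mass nor lymphadenopathy is seen.	tumor	negated
Neither mass nor lymphadenopathy is seen.	lymph_node	negated
No separate tumor nodule in another lobe.	multilobe_cue	negated
Lymphadenopathy is not seen.	lymph_node	negated
A mass is not identified.	tumor	negated
Lymphadenopathy is absent.	lymph_node	negated
Malignancy is ruled out.	tumor	negated
Suspected for malignancy.	tumor	uncertain
Possible mass in the right upper lobe.	tumor	uncertain
Probable lymphadenopathy at station 4R.	lymph_node	uncertain
Suspicion of lymphadenopathy.	lymph_node	uncertain
Suspicious for a lung carcinoma.	tumor	uncertain
Findings suspect of lymphadenopathy.	lymph_node	uncertain
Probably a benign mass.	tumor	uncertain
Likely malignancy.	tumor	uncertain
May represent a mass.	tumor	uncertain
Questionable lymphadenopathy.	lymph_node	uncertain
Suggestive of malignancy.	tumor	uncertain
A mass is suspected.	tumor	uncertain
Lymphadenopathy is possible.	lymph_node	uncertain
There is a spiculated mass in the right upper lobe.	tumor	affirmed
A lung carcinoma with lymphadenopathy.	tumor	affirmed
A lung carcinoma with lymphadenopathy.	lymph_node	affirmed
Enlarged lymph node at station 7.	lymph_node	affirmed
The tumor invades the chest wall.	invasion_target	affirmed
There is lymphadenopathy at station 4R.	lymph_node	affirmed
Malignancy is not excluded.	tumor	affirmed
A mass cannot be excluded.	tumor	affirmed
Lymphadenopathy is not ruled out.	lymph_node	affirmed
No enlarged lymph nodes, but there is a mass.	tumor	affirmed
No enlarged lymph nodes, but there is a mass.	lymph_node	negated
No mass, however there is lymphadenopathy.	lymph_node	affirmed
No mass, however there is lymphadenopathy.	tumor	negated
There is a mass, although no lymphadenopathy.	tumor	affirmed
There is a mass, although no lymphadenopathy.	lymph_node	negated
Suspicion of lymphadenopathy, but the mass is clearly seen.	tumor	affirmed
Suspicion of lymphadenopathy, but the mass is clearly seen.	lymph_node	uncertain
Being suspicious for a lung carcinoma with lymph nodes suspect of lymphadenopathy.	tumor	uncertain
Being suspicious for a lung carcinoma with lymph nodes suspect of lymphadenopathy.	lymph_node	uncertain
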