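# Sentence/phrase pools for the synthetic report generator.  Placeholders in
# curly braces are filled by tnstager.synthetic_reports; every phrase must be
# matchable by the default lexicon so that generated reports round-trip.
language: en

headers:
  ct: {clinical: "Clinical details", technique: "Technique", chest: "Chest", impression: "Impression"}
  petct:
    clinical: "Clinical details"
    technique: "Technique"
    neck: "Neck"
    chest: "Chest"
    abdomen: "Abdomen"
    skeleton: "Skeleton"
    impression: "Impression"

clinical:
  - "Staging for suspected pulmonary malignancy."
  - "Known smoker, staging examination."
  - "Referred for primary staging of a lung lesion."

technique_ct:
  - "Contrast-enhanced CT of the chest."
  - "Helical CT of the chest after intravenous contrast."

technique_petct:
  - "Whole-body 18F-FDG PET-CT from skull base to mid-thigh."
  - "FDG PET-CT examination of the whole body after intravenous tracer injection."

tumor_with_size:
  - "There is a spiculated {tumor_word} in the {lobe_name}, measuring {size_str}."
  - "A {tumor_word} is seen in the {lobe_name} with a diameter of {size_str}."
  - "Irregular {tumor_word} in the {lobe_name} of {size_str}."

tumor_no_size:
  - "There is a central {tumor_word} in the {lobe_name}."
  - "A {tumor_word} is seen in the {lobe_name}."

tumor_word: [mass, tumor, carcinoma]

invasion:
  T2_main_bronchus: "The {tumor_word} extends into the main bronchus."
  T2_visceral_pleura: "The {tumor_word} invades the visceral pleura."
  T2_atelectasis: "There is associated atelectasis."
  T3_chest_wall: "The {tumor_word} invades the chest wall."
  T3_pericardium: "There is invasion of the parietal pericardium."
  T3_phrenic_nerve: "The {tumor_word} involves the phrenic nerve."
  T4_diaphragm: "The {tumor_word} invades the diaphragm."
  T4_carina: "The {tumor_word} extends to the carina."
  T4_mediastinum: "The {tumor_word} invades the mediastinum."
  T4_vertebral_body: "There is destruction of the adjacent vertebral body."

satellite:
  explicit: "There is a satellite nodule in the {lobe_name}."
  implicit: "An additional nodule within the same lobe is seen."

multilobe:
  explicit: "There is a separate tumor nodule in another lobe of the {side} lung."
  implicit: "There is an additional nodule in a different lobe of the {side} lung."

node_ct_pathologic:
  - "There is lymphadenopathy at {station_phrase}, short axis {size} mm."
  - "Enlarged lymph node at {station_phrase}, measuring {size} mm."
  - "Pathologically enlarged lymph nodes at {station_phrase}, short axis {size} mm."

node_pet_avid:
  - "FDG-avid lymph node at {station_phrase}, measuring {size} mm."
  - "There is a hypermetabolic lymph node at {station_phrase}, {size} mm."

node_pet_avid_enlarged:
  - "There is an FDG-avid enlarged lymph node at {station_phrase}, short axis {size} mm."

node_conflict:
  - "Enlarged lymph node at {station_phrase}, {size} mm, without FDG uptake."

node_negated:
  - "No pathologically enlarged lymph nodes."
  - "No suspicious lymph nodes."
  - "No enlarged mediastinal lymph nodes."

blacklist_trap:
  - "Enlarged adrenal gland measuring {size} mm."
  - "Cystic kidney lesion of {size} mm."
  - "Simple hepatic cyst of {size} mm in the liver."

uncertainty_distractor:
  - "Possible subtle second mass at the lung base."
  - "Suspicion of mild lymphadenopathy in the retroperitoneal region."
  - "Questionable small mass in the thyroid."

negation_distractor:
  - "No pleural effusion."
  - "No invasion of the chest wall."
  - "No separate tumor nodule in another lobe."

filler:
  neck: "No cervical abnormality."
  abdomen: "Unremarkable upper abdominal organs."
  skeleton: "No suspicious osseous lesions."

impression:
  - "Known {side} pulmonary malignancy as described above."
  - "{side} lung carcinoma, findings as described."
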