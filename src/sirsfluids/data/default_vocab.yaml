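# Default vocabulary for the SIRS fluid-comparison pipeline.
#
# The outcome/exclusion ICD-9 code sets below are EDITORIAL DEFAULTS: the
# source study's full code lists were published only as supplementary tables
# that are not redistributed here, so these sets carry representative codes
# per category and are intended to be edited per deployment.  The Elixhauser
# section is an ICD-9-CM prefix adaptation of the Quan et al. (2005) mapping,
# with three modifications applied for mutual exclusivity with outcomes:
# renal-failure code 586 removed, peripheral-vascular code 557.9 removed, and
# the fluid/electrolyte-disorder category dropped entirely.
#
# All ICD-9 codes are written WITHOUT dots; matching is by prefix.

fluids:
  # chloride concentration of each fluid type, mmol/L
  catalog:
    calcium_free_balanced: 98.0
    saline_09: 154.0
    lactated_ringers: 109.0
    saline_045: 77.0
    colloid: 154.0
    hypertonic_saline: 513.0
    dextrose_containing: 0.0
    other: 0.0
  # product-name -> fluid_type resolution (lower-cased substring match)
  products:
    plasma-lyte: calcium_free_balanced
    normosol: calcium_free_balanced
    0.9% sodium chloride: saline_09
    normal saline: saline_09
    sodium chloride 0.9%: saline_09
    lactated ringer: lactated_ringers
    0.45% sodium chloride: saline_045
    sodium chloride 0.45%: saline_045
    albumin: colloid
    hetastarch: colloid
    3% sodium chloride: hypertonic_saline
    dextrose: dextrose_containing
    d5w: dextrose_containing
  # fluid types whose bag volumes are summed in exposure windows
  crystalloid_types:
    - calcium_free_balanced
    - saline_09
    - lactated_ringers
    - saline_045

drug_classes:
  antiarrhythmic_iv: [amiodarone, lidocaine, procainamide, ibutilide]
  diuretic: [furosemide, bumetanide, torsemide, hydrochlorothiazide, metolazone]
  vasopressor: [norepinephrine, epinephrine, vasopressin, phenylephrine, dopamine, dobutamine]
  antibiotic: [vancomycin, piperacillin-tazobactam, ceftriaxone, cefepime, levofloxacin, metronidazole, meropenem]
  warfarin: [warfarin]
  iv_magnesium: [magnesium sulfate]
  iv_calcium: [calcium gluconate, calcium chloride]
  potassium_iv_or_oral: [potassium chloride, potassium phosphate]

thresholds:
  troponin_uln_ng_ml: 0.04
  d_dimer_uln_ng_ml: 500.0
  inr_abnormal: 1.5
  bnp_chf_pg_ml: 600.0

echo_order_names: [echocardiogram, echo]

admin_outcomes:
  cardiac: ["410", "427"]
  hemorrhage: ["4590", "5789", "99811"]
  infectious: ["038", "486", "5990", "99591", "99592"]
  gastrointestinal: ["5750", "5601", "5579"]
  neurologic: ["3483", "78039"]
  acute_renal_failure: ["584"]
  respiratory_failure: ["51881", "51882", "51884"]
  new_organ_failure: ["584", "51881", "428", "570", "3483", "78552"]

procedure_sets:
  transfusion: ["9903", "9904"]
  cardiac_surgery: ["351", "352", "361", "3961"]

diagnosis_sets:
  esrd: ["5856"]
  cholecystitis: ["5750", "5751"]

elixhauser:
  congestive_heart_failure: ["39891", "40201", "40211", "40291", "40401", "40403",
    "40411", "40413", "40491", "40493", "4254", "4255", "4256", "4257", "4258",
    "4259", "428"]
  valvular_disease: ["0932", "394", "395", "396", "397", "424", "7463", "7464",
    "7465", "7466", "V422", "V433"]
  pulmonary_circulation: ["4150", "4151", "416", "4170", "4178", "4179"]
  peripheral_vascular: ["0930", "4373", "440", "441", "4431", "4432", "4433",
    "4434", "4435", "4436", "4437", "4438", "4439", "4471", "5571"]
  hypertension: ["401", "402", "403", "404", "405"]
  paralysis: ["3341", "342", "343", "3440", "3441", "3442", "3443", "3444",
    "3445", "3446", "3449"]
  other_neurological: ["3319", "3320", "3321", "3334", "3335", "33392", "334",
    "335", "3362", "340", "341", "345", "3481", "3483", "7803", "7843"]
  chronic_pulmonary: ["4168", "4169", "490", "491", "492", "493", "494", "495",
    "496", "497", "498", "499", "500", "501", "502", "503", "504", "505",
    "5064", "5081", "5088"]
  diabetes_uncomplicated: ["2500", "2501", "2502", "2503"]
  diabetes_complicated: ["2504", "2505", "2506", "2507", "2508", "2509"]
  hypothyroidism: ["2409", "243", "244", "2461", "2468"]
  renal_failure: ["40301", "40311", "40391", "40402", "40403", "40412",
    "40413", "40492", "40493", "585", "5880", "V420", "V451", "V56"]
  liver_disease: ["07022", "07023", "07032", "07033", "07044", "07054", "0706",
    "0709", "4560", "4561", "4562", "570", "571", "5722", "5723", "5724",
    "5728", "5733", "5734", "5738", "5739", "V427"]
  peptic_ulcer: ["5317", "5319", "5327", "5329", "5337", "5339", "5347", "5349"]
  aids: ["042", "043", "044"]
  lymphoma: ["200", "201", "202", "2030", "2386"]
  metastatic_cancer: ["196", "197", "198", "199"]
  solid_tumor: ["140", "141", "142", "143", "144", "145", "146", "147", "148",
    "149", "150", "151", "152", "153", "154", "155", "156", "157", "158",
    "159", "160", "161", "162", "163", "164", "165", "166", "167", "168",
    "169", "170", "171", "172", "174", "175", "176", "179", "180", "181",
    "182", "183", "184", "185", "186", "187", "188", "189", "190", "191",
    "192", "193", "194", "195"]
  rheumatoid_arthritis: ["446", "7010", "7100", "7101", "7102", "7103", "7104",
    "7108", "7109", "7112", "714", "7193", "720", "725", "7285", "72889",
    "72930"]
  coagulopathy: ["286", "2871", "2873", "2874", "2875"]
  obesity: ["2780"]
  weight_loss: ["260", "261", "262", "263", "7832", "7994"]
  blood_loss_anemia: ["2800"]
  deficiency_anemias: ["2801", "2808", "2809", "281"]
  alcohol_abuse: ["2652", "2911", "2912", "2913", "2915", "2918", "2919",
    "30390", "30393", "3050", "3575", "4255", "5353", "5710", "5711", "5712",
    "5713", "980", "V113"]
  drug_abuse: ["292", "304", "3052", "3053", "3054", "3055", "3056", "3057",
    "3058", "3059", "V6542"]
  psychoses: ["2938", "295", "29604", "29614", "29644", "29654", "297", "298"]
  depression: ["2962", "2963", "2965", "3004", "309", "311"]
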