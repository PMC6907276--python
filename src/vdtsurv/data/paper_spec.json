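{
 "n_records": 2453,
 "class_prior": {
  "none": 0.7916836526701998,
  "musculoskeletal": 0.060578393803505916,
  "ophthalmological": 0.03053917651854872,
  "nervous": 0.02274814512841419,
  "cardiovascular": 0.020769139828781084,
  "other": 0.0736814920505503
 },
 "conditionals": {
  "none": {
   "sex": 0.6443,
   "age_ge39": 0.564,
   "bmi": 0.4928,
   "sleep": 0.1673,
   "activity": 0.6842,
   "smoker": 0.1668,
   "alcohol": 0.6776
  },
  "musculoskeletal": {
   "sex": 0.6711,
   "age_ge39": 0.7181,
   "bmi": 0.5503,
   "sleep": 0.2081,
   "activity": 0.3964,
   "smoker": 0.1544,
   "alcohol": 0.6309
  },
  "ophthalmological": {
   "sex": 0.6286,
   "age_ge39": 0.6671,
   "bmi": 0.4571,
   "sleep": 0.2286,
   "activity": 0.7143,
   "smoker": 0.2002,
   "alcohol": 0.6857
  },
  "nervous": {
   "sex": 0.5536,
   "age_ge39": 0.6553,
   "bmi": 0.5357,
   "sleep": 0.3236,
   "activity": 0.5238,
   "smoker": 0.2143,
   "alcohol": 0.6964
  },
  "cardiovascular": {
   "sex": 0.814,
   "age_ge39": 0.6786,
   "bmi": 0.6279,
   "sleep": 0.1628,
   "activity": 0.3659,
   "smoker": 0.2326,
   "alcohol": 0.6981
  },
  "other": {
   "sex": 0.6443,
   "age_ge39": 0.564,
   "bmi": 0.4928,
   "sleep": 0.1673,
   "activity": 0.6842,
   "smoker": 0.1668,
   "alcohol": 0.6776
  }
 },
 "attribute_states": {
  "sex": [
   "man",
   "woman"
  ],
  "age_ge39": [
   "yes",
   "no"
  ],
  "bmi": [
   "normal",
   "overweight"
  ],
  "sleep": [
   "good",
   "variable"
  ],
  "activity": [
   "yes",
   "no"
  ],
  "smoker": [
   "yes",
   "no"
  ],
  "alcohol": [
   "yes",
   "no"
  ]
 }
}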