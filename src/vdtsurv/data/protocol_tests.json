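[
  {"name": "employment history", "specialist": "doctor", "time_cost": 2.5, "money_cost": 1.0509},
  {"name": "personal and family history", "specialist": "doctor", "time_cost": 3.0, "money_cost": 1.2610},
  {"name": "guided exploration", "specialist": "doctor", "time_cost": 4.0, "money_cost": 1.6814},
  {"name": "electrocardiogram", "specialist": "doctor", "time_cost": 3.5, "money_cost": 1.4712},
  {"name": "final report", "specialist": "doctor", "time_cost": 4.5, "money_cost": 1.8916},
  {"name": "eye test", "specialist": "nurse", "time_cost": 3.0, "money_cost": 0.9194},
  {"name": "blood count", "specialist": "nurse", "time_cost": 4.0, "money_cost": 5.2376},
  {"name": "anthropometrics and blood pressure", "specialist": "nurse", "time_cost": 3.5, "money_cost": 1.0726},
  {"name": "spirometry", "specialist": "nurse", "time_cost": 3.0, "money_cost": 0.9194},
  {"name": "audiometry", "specialist": "nurse", "time_cost": 4.0, "money_cost": 1.2258}
]
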