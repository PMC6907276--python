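{
  "strategies": {
    "A": ["employment history", "personal and family history", "guided exploration",
          "electrocardiogram", "final report", "eye test", "blood count",
          "anthropometrics and blood pressure", "spirometry", "audiometry"],
    "B": ["employment history", "personal and family history", "guided exploration",
          "electrocardiogram", "final report", "eye test",
          "anthropometrics and blood pressure", "spirometry", "audiometry"],
    "C": ["employment history", "personal and family history", "guided exploration",
          "electrocardiogram", "final report", "eye test",
          "anthropometrics and blood pressure", "spirometry"],
    "D": ["employment history", "personal and family history", "guided exploration",
          "electrocardiogram", "final report", "eye test",
          "anthropometrics and blood pressure"],
    "E": ["employment history", "personal and family history", "guided exploration",
          "electrocardiogram", "final report", "eye test"],
    "F": ["employment history", "personal and family history", "guided exploration",
          "final report", "eye test"]
  },
  "family": {"A": "extensive", "B": "flexible", "C": "flexible",
             "D": "flexible", "E": "flexible", "F": "optimized"},
  "printed_total_utility": {"A": 51.7309, "B": 32.4933, "C": 37.2675,
                            "D": 33.3481, "E": 28.7755, "F": 23.8043}
}
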