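{
  "version": "kennedy-1993-16item",
  "description": "Simulator Sickness Questionnaire item-to-subscale membership (1-based item indices). Items may load on more than one subscale.",
  "items": [
    "general discomfort", "fatigue", "headache", "eye strain",
    "difficulty focusing", "increased salivation", "sweating", "nausea",
    "difficulty concentrating", "fullness of head", "blurred vision",
    "dizzy (eyes open)", "dizzy (eyes closed)", "vertigo",
    "stomach awareness", "burping"
  ],
  "subscales": {
    "N": [1, 6, 7, 8, 9, 15, 16],
    "O": [1, 2, 3, 4, 5, 9, 11],
    "D": [5, 8, 10, 11, 12, 13, 14]
  },
  "weights": {"N": 9.54, "O": 7.58, "D": 13.92, "T": 3.74}
}
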