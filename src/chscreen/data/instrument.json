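{
  "name": "12-item cluster-headache screening tool",
  "items": [
    {
      "item_id": "image_preference",
      "categories": ["a", "b", "c", "d", "e", "f"],
      "code_map": {"f": 1, "a": 2, "c": 3, "b": 4, "e": 5, "d": 6}
    },
    {
      "item_id": "pain_scale",
      "categories": ["0", "1", "2", "3", "4", "5", "6", "7", "8", "9", "10"],
      "code_map": {"0": 0, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5, "6": 6, "7": 7, "8": 8, "9": 9, "10": 10}
    },
    {
      "item_id": "intensity",
      "categories": ["mild", "moderate", "severe", "very_severe", "excruciating"],
      "code_map": {"mild": 1, "moderate": 2, "severe": 3, "very_severe": 4, "excruciating": 5}
    },
    {
      "item_id": "nature_of_pain",
      "categories": ["throbbing_other", "pressure", "stabbing_burning"],
      "code_map": {"throbbing_other": 1, "pressure": 2, "stabbing_burning": 3}
    },
    {
      "item_id": "description_of_pain",
      "categories": ["pounding_heart_other", "red_hot_poker"],
      "code_map": {"pounding_heart_other": 0, "red_hot_poker": 1}
    },
    {
      "item_id": "restlessness",
      "categories": ["no", "yes"],
      "code_map": {"no": 0, "yes": 1}
    },
    {
      "item_id": "excruciating_agony",
      "categories": ["no", "yes"],
      "code_map": {"no": 0, "yes": 1}
    },
    {
      "item_id": "headache_specific_times",
      "categories": ["no", "yes"],
      "code_map": {"no": 0, "yes": 1}
    },
    {
      "item_id": "strictly_unilateral",
      "categories": ["no", "yes"],
      "code_map": {"no": 0, "yes": 1}
    },
    {
      "item_id": "ipsilateral_autonomic",
      "categories": ["no", "yes"],
      "code_map": {"no": 0, "yes": 1}
    },
    {
      "item_id": "treated_duration",
      "categories": [">3h", "le3h"],
      "code_map": {">3h": 0, "le3h": 1}
    },
    {
      "item_id": "untreated_duration",
      "categories": [">3h", "le3h"],
      "code_map": {">3h": 0, "le3h": 1}
    }
  ]
}
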