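# Canonical simulation spec for the screening-tool study cohort.
# Percentages are the raw printed per-diagnosis frequency distributions; they
# do not always sum to exactly 100 and are renormalised proportionally at load
# time. Items are sampled independently within each patient.
n_ch: 81
n_migraine: 215
subtype_split:
  CH: {chronic: 45, episodic: 36}
  migraine: {chronic: 123, episodic: 92}
sex_split:
  CH: {male: 51, female: 30}
  migraine: {male: 35, female: 180}
age_range: [18, 79]
marginals_percent:
  CH:
    image_preference: {a: 4.7, b: 10.8, c: 3.9, d: 61.9, e: 8.3, f: 10.3}
    pain_scale: {"0": 0.0, "1": 0.0, "2": 0.0, "3": 0.0, "4": 0.0, "5": 1.1,
                 "6": 0.0, "7": 3.3, "8": 3.6, "9": 28.0, "10": 63.9}
    intensity: {mild: 0.0, moderate: 0.0, severe: 7.8, very_severe: 8.6,
                excruciating: 83.6}
    nature_of_pain: {throbbing_other: 18.0, pressure: 14.1,
                     stabbing_burning: 67.8}
    description_of_pain: {pounding_heart_other: 30.8, red_hot_poker: 69.2}
    restlessness: {"no": 10.0, "yes": 90.0}
    excruciating_agony: {"no": 10.0, "yes": 90.0}
    headache_specific_times: {"no": 39.1, "yes": 60.8}
    strictly_unilateral: {"no": 13.3, "yes": 86.6}
    ipsilateral_autonomic: {"no": 3.6, "yes": 96.4}
    treated_duration: {">3h": 0.0, le3h: 100.0}
    untreated_duration: {">3h": 0.0, le3h: 100.0}
  migraine:
    image_preference: {a: 18.9, b: 21.5, c: 23.3, d: 18.0, e: 7.4, f: 14.3}
    pain_scale: {"0": 0.0, "1": 0.0, "2": 0.0, "3": 1.6, "4": 2.0, "5": 3.1,
                 "6": 5.4, "7": 15.8, "8": 33.8, "9": 20.2, "10": 19.9}
    intensity: {mild: 1.1, moderate: 13.8, severe: 35.0, very_severe: 33.6,
                excruciating: 16.4}
    nature_of_pain: {throbbing_other: 40.0, pressure: 33.2,
                     stabbing_burning: 26.7}
    description_of_pain: {pounding_heart_other: 84.4, red_hot_poker: 15.6}
    restlessness: {"no": 56.7, "yes": 43.2}
    excruciating_agony: {"no": 56.7, "yes": 43.2}
    headache_specific_times: {"no": 80.6, "yes": 19.4}
    strictly_unilateral: {"no": 55.5, "yes": 44.5}
    ipsilateral_autonomic: {"no": 57.8, "yes": 42.2}
    treated_duration: {">3h": 75.7, le3h: 24.3}
    untreated_duration: {">3h": 100.0, le3h: 0.0}
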