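# The five harmonized physical-workload exposures.
- exposure_id: heavy_lifting
  label: Heavy lifting
  threshold_text: "daily lifting >20 kg several times per day"
- exposure_id: faster_breathing
  label: Faster breathing due to physical workload
  threshold_text: "at least 1/4 of the time"
- exposure_id: kneeling_squatting
  label: Kneeling or squatting
  threshold_text: "at least 1/4 of the time"
- exposure_id: forward_bent
  label: Forward bent posture
  threshold_text: "at least 1/4 of the time"
- exposure_id: hands_above_shoulder
  label: Hands above shoulder level
  threshold_text: "at least 1/4 of the time"
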