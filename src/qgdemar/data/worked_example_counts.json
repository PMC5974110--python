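{
  "description": "Printed gene counts from a factorial E. coli microarray study of CRP acetylation mutants; inputs to the report arithmetic (overlap percentages, count ratios, spurious-transcription totals).",
  "up_regulated_overlap": {
    "common": 10,
    "total": 160
  },
  "interaction_counts": {
    "cobB_positive": 12,
    "cobB_negative": 38,
    "patZ_positive": 2,
    "patZ_negative": 12
  },
  "mutant_ratio_detection": {
    "deconvolved_up": 94,
    "deconvolved_down": 87,
    "control_chart_up": 22,
    "control_chart_down": 11,
    "control_chart_up_shared": 3,
    "deconvolved_down_specific": 84
  },
  "negative_interaction_annotation": {
    "hypothetical": 24,
    "total": 38
  },
  "spurious_transcription": {
    "exponential_false_negative": 22,
    "exponential_false_positive": 191,
    "stationary_false_negative": 47,
    "stationary_false_positive": 21
  },
  "patZ_enhanced": {
    "from_down_list": 84,
    "added_from_control_chart": 11
  }
}
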