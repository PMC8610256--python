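# Synthetic stand-in for the 12-item PAR-Risk Score point table.
#
# Only the anaemia weight (2 points) is published in the validation study's
# main text; the other eleven weights appear in a supplement that cannot be
# redistributed here.  The weights below are plausible placeholders chosen
# once: integer, anaemia pinned at 2, maximum attainable score (57) above
# both published upper cut-points (10 original, 25 cohort-adapted).
# Replace this file with a transcription of the original table to validate
# the real score.
label: "PAR-Risk Score (synthetic stand-in weights)"
items:
  - {name: los_gt4, points: 6}
  - {name: prior_adm_6m, points: 6}
  - {name: anaemia, points: 2}
  - {name: hypertension, points: 4}
  - {name: heart_failure, points: 5}
  - {name: acute_mi, points: 4}
  - {name: chronic_ihd, points: 3}
  - {name: diabetes_organ, points: 4}
  - {name: cancer, points: 4}
  - {name: metastatic_ca, points: 8}
  - {name: opioids, points: 5}
  - {name: hyperkalaemia, points: 6}
thresholds:
  cut_low: 3
  cut_high: 10
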