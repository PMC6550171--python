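# Identification-criteria rule sets for manuka honey.
#
# Units: chemical markers mg/kg; DNA markers Cq (lower Cq = more DNA).
# Each pathway is a conjunction of per-marker interval predicates; a marker
# not listed in a pathway is unconstrained. A sample is monofloral manuka
# if it satisfies any monofloral pathway, otherwise multifloral manuka if
# it satisfies any multifloral pathway, otherwise not manuka.
#
# option1/option3 come from a 6-level honey-type tree (two pathways, A and
# B, per target class); option2/option4 from a 4-level tree (one pathway
# each). option3/option4 add the 2'-MAP presence gate to option1/option2.
# The kanuka DNA boundary is transcribed literally (">25" in option 1,
# ">=25" in option 3), so Cq exactly 25 behaves differently between them.
# "final" is the published rule set. "option1_exact" is option 1 with the
# unrounded tree thresholds for 3-PA (435 instead of 400, 18.5 instead of
# 20), kept for the threshold-rounding robustness assessment.

option1:
  monofloral:
    - {"3-PA": ">=50", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<30", "kanuka_dna": "<30"}
    - {"3-PA": ">=400", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36", "kanuka_dna": "<25"}
  multifloral:
    - {"3-PA": ">=50 and <400", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36", "kanuka_dna": ">25"}
    - {"3-PA": ">=20 and <50", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}

option2:
  monofloral:
    - {"3-PA": ">=400", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}
  multifloral:
    - {"3-PA": "<400", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}

option3:
  monofloral:
    - {"3-PA": ">=50", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<30", "kanuka_dna": "<25"}
    - {"3-PA": ">=400", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36", "kanuka_dna": ">=25"}
  multifloral:
    - {"3-PA": ">=50 and <400", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36", "kanuka_dna": ">=25"}
    - {"3-PA": ">=20 and <50", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}

option4:
  monofloral:
    - {"3-PA": ">=400", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}
  multifloral:
    - {"3-PA": "<400", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}

final:
  monofloral:
    - {"3-PA": ">=400", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}
  multifloral:
    - {"3-PA": ">=20 and <400", "2'-MAP": ">=1", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}

option1_exact:
  monofloral:
    - {"3-PA": ">=50", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<30", "kanuka_dna": "<30"}
    - {"3-PA": ">=435", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36", "kanuka_dna": "<25"}
  multifloral:
    - {"3-PA": ">=50 and <435", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36", "kanuka_dna": ">25"}
    - {"3-PA": ">=18.5 and <50", "2-MBA": ">=1", "4-HPA": ">=1", "manuka_dna": "<36"}
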