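# Default disorder catalogue: ICD-10 prefix definitions.
# Mental-disorder definitions follow the common register-based case
# definitions for the six major psychiatric disorders; cardiometabolic
# entries are placeholder ICD-10 chapter prefixes for widely studied
# conditions.  Prefixes are dot-stripped and uppercase; ranges such as
# "F30-F39" are expanded at load time.  ICD-8/9 equivalents are left to
# user-supplied catalogues.
ADHD:
  class: mental
  icd10: ["F900"]
AN:
  class: mental
  icd10: ["F500", "F501"]
ASD:
  class: mental
  icd10: ["F840", "F841", "F845", "F848", "F849"]
AFF:
  class: mental
  icd10: ["F30-F39"]
BD:
  class: mental
  icd10: ["F30-F31"]
SCZ:
  class: mental
  icd10: ["F20"]
T2D:
  class: cardiometabolic
  icd10: ["E11"]
T1D:
  class: cardiometabolic
  icd10: ["E10"]
HYPERTENSION:
  class: cardiometabolic
  icd10: ["I10-I15"]
CAD:
  class: cardiometabolic
  icd10: ["I20-I25"]
AFIB:
  class: cardiometabolic
  icd10: ["I48"]
HF:
  class: cardiometabolic
  icd10: ["I50"]
STROKE:
  class: cardiometabolic
  icd10: ["I60-I64"]
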