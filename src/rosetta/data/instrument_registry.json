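{
 "format": "rosetta-registry/1",
 "registry": [
  {
   "instrument": "ADI-R",
   "version": "Standard",
   "reporter": "clinician",
   "n_items": 93,
   "scale": {
    "kind": "quality",
    "labels": [
     "No difficulty",
     "Mild difficulty",
     "Definite difficulty",
     "Severe difficulty"
    ]
   }
  },
  {
   "instrument": "ADOS-2",
   "version": "Module 1",
   "reporter": "clinician",
   "n_items": 29,
   "scale": {
    "kind": "quality",
    "labels": [
     "Typical",
     "Mildly atypical",
     "Markedly atypical",
     "Severely atypical"
    ]
   }
  },
  {
   "instrument": "ADOS-2",
   "version": "Module 2",
   "reporter": "clinician",
   "n_items": 28,
   "scale": {
    "kind": "quality",
    "labels": [
     "Typical",
     "Mildly atypical",
     "Markedly atypical",
     "Severely atypical"
    ]
   }
  },
  {
   "instrument": "ADOS-2",
   "version": "Module 3",
   "reporter": "clinician",
   "n_items": 28,
   "scale": {
    "kind": "quality",
    "labels": [
     "Typical",
     "Mildly atypical",
     "Markedly atypical",
     "Severely atypical"
    ]
   }
  },
  {
   "instrument": "ADOS-2",
   "version": "Module 4",
   "reporter": "clinician",
   "n_items": 31,
   "scale": {
    "kind": "quality",
    "labels": [
     "Typical",
     "Mildly atypical",
     "Markedly atypical",
     "Severely atypical"
    ]
   }
  },
  {
   "instrument": "BASC-3",
   "version": "Preschool",
   "reporter": "parent",
   "n_items": 139,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Never",
     "Sometimes",
     "Often",
     "Almost always"
    ]
   }
  },
  {
   "instrument": "BASC-3",
   "version": "Child",
   "reporter": "parent",
   "n_items": 175,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Never",
     "Sometimes",
     "Often",
     "Almost always"
    ]
   }
  },
  {
   "instrument": "BASC-3",
   "version": "Adolescent",
   "reporter": "parent",
   "n_items": 173,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Never",
     "Sometimes",
     "Often",
     "Almost always"
    ]
   }
  },
  {
   "instrument": "BRIEF2",
   "version": "Parent",
   "reporter": "parent",
   "n_items": 63,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Never",
     "Sometimes",
     "Often"
    ]
   }
  },
  {
   "instrument": "CBCL",
   "version": "Preschool",
   "reporter": "parent",
   "n_items": 100,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Not true",
     "Somewhat true",
     "Very true"
    ]
   }
  },
  {
   "instrument": "CBCL",
   "version": "School-Age",
   "reporter": "parent",
   "n_items": 113,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Not true",
     "Somewhat true",
     "Very true"
    ]
   }
  },
  {
   "instrument": "Conners 3",
   "version": "Parent",
   "reporter": "parent",
   "n_items": 110,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Never",
     "Sometimes",
     "Often",
     "Almost always"
    ]
   }
  },
  {
   "instrument": "SRS-2",
   "version": "Preschool",
   "reporter": "parent",
   "n_items": 65,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Not true",
     "Sometimes true",
     "Often true",
     "Almost always true"
    ]
   }
  },
  {
   "instrument": "SRS-2",
   "version": "School-Age",
   "reporter": "parent",
   "n_items": 65,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Not true",
     "Sometimes true",
     "Often true",
     "Almost always true"
    ]
   }
  },
  {
   "instrument": "VADRS",
   "version": "Parent",
   "reporter": "parent",
   "n_items": 55,
   "scale": {
    "kind": "frequency",
    "labels": [
     "Never",
     "Sometimes",
     "Often",
     "Almost always"
    ]
   }
  }
 ]
}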