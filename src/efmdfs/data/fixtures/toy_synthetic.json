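{
 "metabolites": [
  {
   "id": "A",
   "external": false
  },
  {
   "id": "B",
   "external": false
  },
  {
   "id": "C",
   "external": false
  },
  {
   "id": "D",
   "external": false
  },
  {
   "id": "E",
   "external": false
  },
  {
   "id": "F",
   "external": false
  },
  {
   "id": "G",
   "external": false
  },
  {
   "id": "H",
   "external": false
  }
 ],
 "reactions": [
  {
   "id": "R01",
   "stoich": {
    "A": 1.0
   },
   "reversible": false
  },
  {
   "id": "R02",
   "stoich": {
    "A": -1.0,
    "B": 1.0
   },
   "reversible": false
  },
  {
   "id": "R03",
   "stoich": {
    "B": -1.0,
    "D": 1.0
   },
   "reversible": false
  },
  {
   "id": "R04",
   "stoich": {
    "A": -1.0,
    "C": 1.0
   },
   "reversible": false
  },
  {
   "id": "R05",
   "stoich": {
    "B": -1.0,
    "E": 1.0
   },
   "reversible": false
  },
  {
   "id": "R06",
   "stoich": {
    "D": -1.0,
    "F": 1.0
   },
   "reversible": false
  },
  {
   "id": "R07",
   "stoich": {
    "E": -1.0,
    "F": 1.0
   },
   "reversible": false
  },
  {
   "id": "R08",
   "stoich": {
    "C": -1.0,
    "F": 1.0
   },
   "reversible": false
  },
  {
   "id": "R09",
   "stoich": {
    "C": -1.0,
    "G": 1.0
   },
   "reversible": false
  },
  {
   "id": "R10",
   "stoich": {
    "F": 1.0,
    "G": -1.0
   },
   "reversible": false
  },
  {
   "id": "R11",
   "stoich": {
    "F": -1.0,
    "H": 1.0
   },
   "reversible": false
  },
  {
   "id": "R12",
   "stoich": {
    "H": -1.0
   },
   "reversible": false
  },
  {
   "id": "R13",
   "stoich": {
    "F": -1.0
   },
   "reversible": false
  },
  {
   "id": "R14",
   "stoich": {
    "F": 1.0,
    "H": -1.0
   },
   "reversible": false
  }
 ]
}
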