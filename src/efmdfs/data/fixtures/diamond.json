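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
  }
 ],
 "reactions": [
  {
   "id": "r1",
   "stoich": {
    "A": 1.0
   },
   "reversible": false
  },
  {
   "id": "r2",
   "stoich": {
    "A": -1.0,
    "B": 1.0
   },
   "reversible": false
  },
  {
   "id": "r3",
   "stoich": {
    "A": -1.0,
    "C": 1.0
   },
   "reversible": false
  },
  {
   "id": "r4",
   "stoich": {
    "B": -1.0,
    "D": 1.0
   },
   "reversible": false
  },
  {
   "id": "r5",
   "stoich": {
    "C": -1.0,
    "D": 1.0
   },
   "reversible": false
  },
  {
   "id": "r6",
   "stoich": {
    "D": -1.0
   },
   "reversible": false
  }
 ]
}
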