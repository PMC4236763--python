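{
 "metabolites": [
  {
   "id": "A",
   "external": false
  },
  {
   "id": "B",
   "external": false
  }
 ],
 "reactions": [
  {
   "id": "R1",
   "stoich": {
    "A": 1.0
   },
   "reversible": false
  },
  {
   "id": "R2",
   "stoich": {
    "A": -1.0,
    "B": 1.0
   },
   "reversible": false
  },
  {
   "id": "R3",
   "stoich": {
    "B": -1.0
   },
   "reversible": false
  }
 ]
}
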