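{
 "comment": "Idealized pyrimidine base geometries (standard reference frame, ring in z=0 plane, Angstrom). 'breadth' marks the default breadth atom set: heavy atoms plus the C5 substituent; glycosidic C1' and ring/amine hydrogens excluded.",
 "bases": {
  "C": {
   "atoms": [
    {
     "name": "C1'",
     "element": "C",
     "coord": [
      -2.477,
      5.399,
      0.0
     ],
     "role": "glycosidic",
     "breadth": false
    },
    {
     "name": "N1",
     "element": "N",
     "coord": [
      -1.285,
      4.542,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C2",
     "element": "C",
     "coord": [
      -1.472,
      3.158,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "O2",
     "element": "O",
     "coord": [
      -2.628,
      2.709,
      0.0
     ],
     "role": "exocyclic",
     "breadth": true
    },
    {
     "name": "N3",
     "element": "N",
     "coord": [
      -0.391,
      2.344,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C4",
     "element": "C",
     "coord": [
      0.837,
      2.868,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "N4",
     "element": "N",
     "coord": [
      1.875,
      2.027,
      0.0
     ],
     "role": "exocyclic",
     "breadth": true
    },
    {
     "name": "C5",
     "element": "C",
     "coord": [
      1.056,
      4.275,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C6",
     "element": "C",
     "coord": [
      -0.023,
      5.068,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "H5",
     "element": "H",
     "coord": [
      2.0544,
      4.6869,
      0.0
     ],
     "role": "substituent",
     "breadth": true
    },
    {
     "name": "H6",
     "element": "H",
     "coord": [
      0.1057,
      6.1403,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "H41",
     "element": "H",
     "coord": [
      2.818,
      2.3887,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "H42",
     "element": "H",
     "coord": [
      1.7167,
      1.0295,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    }
   ],
   "rotatable": null
  },
  "5mC": {
   "atoms": [
    {
     "name": "C1'",
     "element": "C",
     "coord": [
      -2.477,
      5.399,
      0.0
     ],
     "role": "glycosidic",
     "breadth": false
    },
    {
     "name": "N1",
     "element": "N",
     "coord": [
      -1.285,
      4.542,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C2",
     "element": "C",
     "coord": [
      -1.472,
      3.158,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "O2",
     "element": "O",
     "coord": [
      -2.628,
      2.709,
      0.0
     ],
     "role": "exocyclic",
     "breadth": true
    },
    {
     "name": "N3",
     "element": "N",
     "coord": [
      -0.391,
      2.344,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C4",
     "element": "C",
     "coord": [
      0.837,
      2.868,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "N4",
     "element": "N",
     "coord": [
      1.875,
      2.027,
      0.0
     ],
     "role": "exocyclic",
     "breadth": true
    },
    {
     "name": "C5",
     "element": "C",
     "coord": [
      1.056,
      4.275,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C6",
     "element": "C",
     "coord": [
      -0.023,
      5.068,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "H6",
     "element": "H",
     "coord": [
      0.1057,
      6.1403,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "H41",
     "element": "H",
     "coord": [
      2.818,
      2.3887,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "H42",
     "element": "H",
     "coord": [
      1.7167,
      1.0295,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "C7",
     "element": "C",
     "coord": [
      2.4389,
      4.8456,
      0.0
     ],
     "role": "substituent",
     "breadth": true
    },
    {
     "name": "H71",
     "element": "H",
     "coord": [
      2.7753,
      4.9843,
      -1.0275
     ],
     "role": "substituent_hydrogen",
     "breadth": false
    },
    {
     "name": "H72",
     "element": "H",
     "coord": [
      2.4359,
      5.8069,
      0.5137
     ],
     "role": "substituent_hydrogen",
     "breadth": false
    },
    {
     "name": "H73",
     "element": "H",
     "coord": [
      3.1146,
      4.1618,
      0.5137
     ],
     "role": "substituent_hydrogen",
     "breadth": false
    }
   ],
   "rotatable": null
  },
  "5hmC": {
   "atoms": [
    {
     "name": "C1'",
     "element": "C",
     "coord": [
      -2.477,
      5.399,
      0.0
     ],
     "role": "glycosidic",
     "breadth": false
    },
    {
     "name": "N1",
     "element": "N",
     "coord": [
      -1.285,
      4.542,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C2",
     "element": "C",
     "coord": [
      -1.472,
      3.158,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "O2",
     "element": "O",
     "coord": [
      -2.628,
      2.709,
      0.0
     ],
     "role": "exocyclic",
     "breadth": true
    },
    {
     "name": "N3",
     "element": "N",
     "coord": [
      -0.391,
      2.344,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C4",
     "element": "C",
     "coord": [
      0.837,
      2.868,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "N4",
     "element": "N",
     "coord": [
      1.875,
      2.027,
      0.0
     ],
     "role": "exocyclic",
     "breadth": true
    },
    {
     "name": "C5",
     "element": "C",
     "coord": [
      1.056,
      4.275,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "C6",
     "element": "C",
     "coord": [
      -0.023,
      5.068,
      0.0
     ],
     "role": "ring",
     "breadth": true
    },
    {
     "name": "H6",
     "element": "H",
     "coord": [
      0.1057,
      6.1403,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "H41",
     "element": "H",
     "coord": [
      2.818,
      2.3887,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "H42",
     "element": "H",
     "coord": [
      1.7167,
      1.0295,
      0.0
     ],
     "role": "hydrogen",
     "breadth": false
    },
    {
     "name": "C7",
     "element": "C",
     "coord": [
      2.4389,
      4.8456,
      0.0
     ],
     "role": "substituent",
     "breadth": true
    },
    {
     "name": "O7",
     "element": "O",
     "coord": [
      2.9019,
      5.0366,
      -1.3394
     ],
     "role": "substituent",
     "breadth": true
    }
   ],
   "rotatable": {
    "axis": [
     "C5",
     "C7"
    ],
    "moving": [
     "O7"
    ],
    "grid_step_deg": 10
   }
  }
 }
}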