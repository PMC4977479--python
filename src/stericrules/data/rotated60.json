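{
 "type": "adjacency",
 "name": "rotated60",
 "note": "Transcription of the published 60-degree rule-table hindrance map; directional for pair B-D, hence stored as an explicit adjacency rather than a distance table.",
 "nominal_cutoff_nm": 8.1,
 "strands": [
  {
   "strand": "I",
   "regions": [
    "A",
    "B",
    "C",
    "D",
    "E",
    "F"
   ],
   "neighbors": {
    "A": [
     "B",
     "C",
     "D"
    ],
    "B": [
     "A",
     "C"
    ],
    "C": [
     "A",
     "B",
     "D"
    ],
    "D": [
     "A",
     "B",
     "C",
     "E"
    ],
    "E": [
     "D",
     "F"
    ],
    "F": [
     "E"
    ]
   }
  },
  {
   "strand": "II",
   "regions": [
    "A",
    "B",
    "C",
    "D",
    "E",
    "F"
   ],
   "neighbors": {
    "A": [
     "B",
     "C",
     "D"
    ],
    "B": [
     "A",
     "C"
    ],
    "C": [
     "A",
     "B",
     "D"
    ],
    "D": [
     "A",
     "B",
     "C",
     "E"
    ],
    "E": [
     "D",
     "F"
    ],
    "F": [
     "E"
    ]
   }
  }
 ]
}
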