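{
 "type": "geometry",
 "name": "native",
 "note": "Synthetic reconstruction: pairwise distances chosen to reproduce the published steric adjacency and cutoff-distance interval for this conformation; they are not measured values.",
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
   "pairs": [
    {
     "a": "A",
     "b": "B",
     "linear_nm": 4.6,
     "curvature": "negative"
    },
    {
     "a": "A",
     "b": "C",
     "linear_nm": 7.9,
     "path_nm": 8.8,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "D",
     "linear_nm": 11.7,
     "path_nm": 13.0,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "E",
     "linear_nm": 16.2,
     "path_nm": 18.0,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "F",
     "linear_nm": 19.8,
     "path_nm": 22.0,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "C",
     "linear_nm": 5.2,
     "curvature": "negative"
    },
    {
     "a": "B",
     "b": "D",
     "linear_nm": 8.6,
     "path_nm": 9.5,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "E",
     "linear_nm": 12.6,
     "path_nm": 14.0,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "F",
     "linear_nm": 17.1,
     "path_nm": 19.0,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "D",
     "linear_nm": 5.5,
     "curvature": "negative"
    },
    {
     "a": "C",
     "b": "E",
     "linear_nm": 9.2,
     "path_nm": 10.2,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "F",
     "linear_nm": 13.5,
     "path_nm": 15.0,
     "curvature": "nonnegative"
    },
    {
     "a": "D",
     "b": "E",
     "linear_nm": 7.0,
     "curvature": "negative"
    },
    {
     "a": "D",
     "b": "F",
     "linear_nm": 8.9,
     "path_nm": 9.9,
     "curvature": "nonnegative"
    },
    {
     "a": "E",
     "b": "F",
     "linear_nm": 4.9,
     "curvature": "negative"
    }
   ]
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
   "pairs": [
    {
     "a": "A",
     "b": "B",
     "linear_nm": 4.6,
     "curvature": "negative"
    },
    {
     "a": "A",
     "b": "C",
     "linear_nm": 7.9,
     "path_nm": 8.8,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "D",
     "linear_nm": 11.7,
     "path_nm": 13.0,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "E",
     "linear_nm": 16.2,
     "path_nm": 18.0,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "F",
     "linear_nm": 19.8,
     "path_nm": 22.0,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "C",
     "linear_nm": 5.2,
     "curvature": "negative"
    },
    {
     "a": "B",
     "b": "D",
     "linear_nm": 8.6,
     "path_nm": 9.5,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "E",
     "linear_nm": 12.6,
     "path_nm": 14.0,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "F",
     "linear_nm": 17.1,
     "path_nm": 19.0,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "D",
     "linear_nm": 5.6,
     "curvature": "negative"
    },
    {
     "a": "C",
     "b": "E",
     "linear_nm": 9.2,
     "path_nm": 10.2,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "F",
     "linear_nm": 13.5,
     "path_nm": 15.0,
     "curvature": "nonnegative"
    },
    {
     "a": "D",
     "b": "E",
     "linear_nm": 7.0,
     "curvature": "negative"
    },
    {
     "a": "D",
     "b": "F",
     "linear_nm": 8.9,
     "path_nm": 9.9,
     "curvature": "nonnegative"
    },
    {
     "a": "E",
     "b": "F",
     "linear_nm": 4.9,
     "curvature": "negative"
    }
   ]
  }
 ]
}
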