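{
 "type": "geometry",
 "name": "s_shaped",
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
     "linear_nm": 4.5,
     "curvature": "negative"
    },
    {
     "a": "A",
     "b": "C",
     "linear_nm": 7.6,
     "path_nm": 8.4,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "D",
     "linear_nm": 11.2,
     "path_nm": 12.5,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "E",
     "linear_nm": 15.3,
     "path_nm": 17.0,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "F",
     "linear_nm": 18.9,
     "path_nm": 21.0,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "C",
     "linear_nm": 5.8,
     "curvature": "negative"
    },
    {
     "a": "B",
     "b": "D",
     "linear_nm": 8.2,
     "path_nm": 9.1,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "E",
     "linear_nm": 11.9,
     "path_nm": 13.2,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "F",
     "linear_nm": 16.0,
     "path_nm": 17.8,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "D",
     "linear_nm": 5.4,
     "curvature": "negative"
    },
    {
     "a": "C",
     "b": "E",
     "linear_nm": 8.8,
     "path_nm": 9.8,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "F",
     "linear_nm": 13.0,
     "path_nm": 14.4,
     "curvature": "nonnegative"
    },
    {
     "a": "D",
     "b": "E",
     "linear_nm": 6.8,
     "curvature": "negative"
    },
    {
     "a": "D",
     "b": "F",
     "linear_nm": 9.5,
     "path_nm": 10.6,
     "curvature": "nonnegative"
    },
    {
     "a": "E",
     "b": "F",
     "linear_nm": 5.0,
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
     "linear_nm": 4.5,
     "curvature": "negative"
    },
    {
     "a": "A",
     "b": "C",
     "linear_nm": 7.6,
     "path_nm": 8.4,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "D",
     "linear_nm": 11.2,
     "path_nm": 12.5,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "E",
     "linear_nm": 15.3,
     "path_nm": 17.0,
     "curvature": "nonnegative"
    },
    {
     "a": "A",
     "b": "F",
     "linear_nm": 18.9,
     "path_nm": 21.0,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "C",
     "linear_nm": 5.8,
     "curvature": "negative"
    },
    {
     "a": "B",
     "b": "D",
     "linear_nm": 8.2,
     "path_nm": 9.1,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "E",
     "linear_nm": 11.9,
     "path_nm": 13.2,
     "curvature": "nonnegative"
    },
    {
     "a": "B",
     "b": "F",
     "linear_nm": 16.0,
     "path_nm": 17.8,
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
     "linear_nm": 8.8,
     "path_nm": 9.8,
     "curvature": "nonnegative"
    },
    {
     "a": "C",
     "b": "F",
     "linear_nm": 13.0,
     "path_nm": 14.4,
     "curvature": "nonnegative"
    },
    {
     "a": "D",
     "b": "E",
     "linear_nm": 6.8,
     "curvature": "negative"
    },
    {
     "a": "D",
     "b": "F",
     "linear_nm": 9.5,
     "path_nm": 10.6,
     "curvature": "nonnegative"
    },
    {
     "a": "E",
     "b": "F",
     "linear_nm": 5.0,
     "curvature": "negative"
    }
   ]
  }
 ]
}
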