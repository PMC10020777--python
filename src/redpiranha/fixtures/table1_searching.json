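{
 "name": "table1_searching",
 "objective": "example_quadratic",
 "lower": [
  -5.0,
  -5.0
 ],
 "upper": [
  5.0,
  5.0
 ],
 "n": 10,
 "xi": 4,
 "lam": 3,
 "z": 11,
 "agents": [
  "P1",
  "P2",
  "P3",
  "P4",
  "P5",
  "P6",
  "P7",
  "P8",
  "P9",
  "P10"
 ],
 "initial": {
  "P1": {
   "position": [
    -0.451,
    1.913
   ],
   "objective": 14.476
  },
  "P2": {
   "position": [
    1.983,
    0.562
   ],
   "objective": 12.348
  },
  "P3": {
   "position": [
    1.446,
    3.449
   ],
   "objective": 28.6878
  },
  "P4": {
   "position": [
    3.114,
    -3.367
   ],
   "objective": 27.279
  },
  "P5": {
   "position": [
    1.432,
    0.488
   ],
   "objective": 9.406
  },
  "P6": {
   "position": [
    -0.345,
    3.451
   ],
   "objective": 29.333
  },
  "P7": {
   "position": [
    4.378,
    -1.046
   ],
   "objective": 32.412
  },
  "P8": {
   "position": [
    -2.876,
    2.345
   ],
   "objective": 27.143
  },
  "P9": {
   "position": [
    4.129,
    -2.491
   ],
   "objective": 34.833
  },
  "P10": {
   "position": [
    4.345,
    -3.554
   ],
   "objective": 44.426
  }
 },
 "iterations": [
  {
   "P1": {
    "scout": "P2",
    "A": -1.8945,
    "C": 0.568,
    "position": [
     4.972,
     3.582
    ],
    "objective": 47.014,
    "update_checked": true
   },
   "P2": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     1.983,
     0.562
    ],
    "objective": 12.348,
    "update_checked": true
   },
   "P3": {
    "scout": "P6",
    "A": 1.766,
    "C": 1.802,
    "position": [
     -3.997,
     -1.44
    ],
    "objective": 1.54,
    "update_checked": true
   },
   "P4": {
    "scout": "P2",
    "A": 1.987,
    "C": 0.876,
    "position": [
     -0.753,
     -5.0
    ],
    "objective": 3.296,
    "update_checked": true
   },
   "P5": {
    "scout": "P9",
    "A": -1.235,
    "C": 0.674,
    "position": [
     5.0,
     0.185
    ],
    "objective": 37.849,
    "update_checked": true
   },
   "P6": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     -0.345,
     3.451
    ],
    "objective": 29.333,
    "update_checked": true
   },
   "P7": {
    "scout": "P2",
    "A": 1.832,
    "C": 1.566,
    "position": [
     -0.3487,
     -2.967
    ],
    "objective": -1.675,
    "update_checked": true
   },
   "P8": {
    "scout": "P6",
    "A": -1.566,
    "C": 0.934,
    "position": [
     3.654,
     4.826
    ],
    "objective": 48.62,
    "update_checked": true
   },
   "P9": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     4.129,
     -2.491
    ],
    "objective": 34.833,
    "update_checked": true
   },
   "P10": {
    "scout": "P9",
    "A": 1.331,
    "C": 0.778,
    "position": [
     2.621,
     -4.642
    ],
    "objective": 30.258,
    "update_checked": true
   }
  },
  {
   "P1": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     4.972,
     3.582
    ],
    "objective": 47.014,
    "update_checked": true
   },
   "P2": {
    "scout": "P1",
    "A": 1.433,
    "C": 1.561,
    "position": [
     -3.308,
     -3.625
    ],
    "objective": -6.024,
    "update_checked": true
   },
   "P3": {
    "scout": "P4",
    "A": -1.421,
    "C": 0.942,
    "position": [
     3.919,
     -0.353
    ],
    "objective": 26.293,
    "update_checked": true
   },
   "P4": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     -0.753,
     -5.0
    ],
    "objective": 3.296,
    "update_checked": true
   },
   "P5": {
    "scout": "P10",
    "A": -1.366,
    "C": 1.691,
    "position": [
     3.397,
     5.0
    ],
    "objective": 49.349,
    "update_checked": true
   },
   "P6": {
    "scout": "P4",
    "A": 1.278,
    "C": 1.256,
    "position": [
     -1.521,
     -5.0
    ],
    "objective": -0.334,
    "update_checked": true
   },
   "P7": {
    "scout": "P1",
    "A": -1.061,
    "C": 0.072,
    "position": [
     5.0,
     5.0
    ],
    "objective": 58.0,
    "update_checked": true
   },
   "P8": {
    "scout": "P10",
    "A": -1.211,
    "C": 1.334,
    "position": [
     2.812,
     5.0
    ],
    "objective": 47.471,
    "update_checked": true
   },
   "P9": {
    "scout": "P4",
    "A": -1.088,
    "C": 0.131,
    "position": [
     3.847,
     -3.002
    ],
    "objective": 34.046,
    "update_checked": true
   },
   "P10": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     2.621,
     -4.642
    ],
    "objective": 30.258,
    "update_checked": true
   }
  },
  {
   "P1": {
    "scout": "P8",
    "A": 1.433,
    "C": 1.561,
    "position": [
     1.977,
     -1.052
    ],
    "objective": 9.841,
    "update_checked": true
   },
   "P2": {
    "scout": "P8",
    "A": 1.021,
    "C": 0.464,
    "position": [
     -1.8948,
     -1.07
    ],
    "objective": -2.36,
    "update_checked": true
   },
   "P3": {
    "scout": "P7",
    "A": 1.366,
    "C": 0.691,
    "position": [
     4.366,
     -0.202
    ],
    "objective": 30.909,
    "update_checked": true
   },
   "P4": {
    "scout": "P5",
    "A": 1.278,
    "C": 0.256,
    "position": [
     1.323,
     -3.023
    ],
    "objective": 8.442,
    "update_checked": true
   },
   "P5": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     3.397,
     5.0
    ],
    "objective": 49.349,
    "update_checked": true
   },
   "P6": {
    "scout": "P5",
    "A": 1.061,
    "C": 0.872,
    "position": [
     -1.36,
     -4.931
    ],
    "objective": 0.014,
    "update_checked": true
   },
   "P7": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     5.0,
     5.0
    ],
    "objective": 58.0,
    "update_checked": true
   },
   "P8": {
    "scout": null,
    "A": null,
    "C": null,
    "position": [
     2.812,
     5.0
    ],
    "objective": 47.471,
    "update_checked": true
   },
   "P9": {
    "scout": "P7",
    "A": 1.011,
    "C": 0.934,
    "position": [
     4.168,
     -2.756
    ],
    "objective": 36.767,
    "update_checked": true
   },
   "P10": {
    "scout": "P7",
    "A": 1.188,
    "C": 0.131,
    "position": [
     2.664,
     -1.293
    ],
    "objective": 15.369,
    "update_checked": true
   }
  }
 ],
 "best_after": {
  "P1": {
   "position": [
    1.977,
    -1.052
   ],
   "objective": 9.841
  },
  "P2": {
   "position": [
    -3.308,
    -3.625
   ],
   "objective": -6.024
  },
  "P3": {
   "position": [
    -3.997,
    -1.44
   ],
   "objective": 1.54
  },
  "P4": {
   "position": [
    -0.753,
    -5.0
   ],
   "objective": 3.296
  },
  "P5": {
   "position": [
    1.432,
    0.488
   ],
   "objective": 9.406
  },
  "P6": {
   "position": [
    -1.521,
    -5.0
   ],
   "objective": -0.334
  },
  "P7": {
   "position": [
    -0.3487,
    -2.967
   ],
   "objective": -1.675
  },
  "P8": {
   "position": [
    -2.876,
    2.345
   ],
   "objective": 27.143
  },
  "P9": {
   "position": [
    3.847,
    -3.002
   ],
   "objective": 34.046
  },
  "P10": {
   "position": [
    2.664,
    -1.293
   ],
   "objective": 15.369
  }
 }
}
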