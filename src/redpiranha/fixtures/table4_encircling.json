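{
 "name": "table4_encircling",
 "objective": "example_quadratic",
 "lower": [
  -5.0,
  -5.0
 ],
 "upper": [
  5.0,
  5.0
 ],
 "k": 3,
 "b": 1.0,
 "z_enc": 3,
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
 },
 "iterations": [
  {
   "t": 1,
   "l": 0.3333,
   "prey": [
    -1.726,
    -3.864
   ],
   "prey_checked": true,
   "cells": {
    "P1": {
     "D": [
      3.703,
      2.812
     ],
     "position": [
      2.482,
      -0.669
     ],
     "objective": 13.556,
     "d_checked": true
    },
    "P2": {
     "D": [
      1.582,
      0.239
     ],
     "position": [
      0.072,
      -3.592
     ],
     "objective": 1.943,
     "d_checked": true
    },
    "P3": {
     "D": [
      2.271,
      2.424
     ],
     "position": [
      0.855,
      -1.109
     ],
     "objective": 3.182,
     "d_checked": true
    },
    "P4": {
     "D": [
      0.973,
      1.136
     ],
     "position": [
      -0.62,
      -2.573
     ],
     "objective": -3.124,
     "d_checked": true
    },
    "P5": {
     "D": [
      3.158,
      4.352
     ],
     "position": [
      1.863,
      1.082
     ],
     "objective": 13.676,
     "d_checked": true
    },
    "P6": {
     "D": [
      0.205,
      1.136
     ],
     "position": [
      -1.493,
      -2.573
     ],
     "objective": -5.27,
     "d_checked": true
    },
    "P7": {
     "D": [
      1.377,
      0.8947
     ],
     "position": [
      -0.161,
      -2.845
     ],
     "objective": -1.04,
     "d_checked": true
    },
    "P8": {
     "D": [
      1.15,
      6.209
     ],
     "position": [
      -0.419,
      3.192
     ],
     "objective": 26.629,
     "d_checked": true
    },
    "P9": {
     "D": [
      5.573,
      0.862
     ],
     "position": [
      4.607,
      -2.884
     ],
     "objective": 43.509,
     "d_checked": true
    },
    "P10": {
     "D": [
      4.39,
      2.571
     ],
     "position": [
      3.263,
      -0.942
     ],
     "objective": 20.364,
     "d_checked": true
    }
   }
  },
  {
   "t": 2,
   "l": -0.3333,
   "prey": [
    -0.758,
    -2.664
   ],
   "prey_checked": true,
   "cells": {
    "P1": {
     "D": [
      3.24,
      1.995
     ],
     "position": [
      1.132,
      -1.5
     ],
     "objective": 4.495,
     "d_checked": true
    },
    "P2": {
     "D": [
      0.83,
      0.929
     ],
     "position": [
      -0.274,
      -2.122
     ],
     "objective": -2.039,
     "d_checked": true
    },
    "P3": {
     "D": [
      1.613,
      1.554
     ],
     "position": [
      0.183,
      -1.757
     ],
     "objective": -0.22,
     "d_checked": true
    },
    "P4": {
     "D": [
      0.138,
      0.091
     ],
     "position": [
      -0.678,
      -2.617
     ],
     "objective": -3.292,
     "d_checked": true
    },
    "P5": {
     "D": [
      2.621,
      3.745
     ],
     "position": [
      0.771,
      -0.479
     ],
     "objective": 3.82,
     "d_checked": true
    },
    "P6": {
     "D": [
      0.735,
      0.091
     ],
     "position": [
      -0.329,
      -2.611
     ],
     "objective": -2.037,
     "d_checked": true
    },
    "P7": {
     "D": [
      0.597,
      0.181
     ],
     "position": [
      -0.41,
      -2.558
     ],
     "objective": -2.388,
     "d_checked": true
    },
    "P8": {
     "D": [
      0.339,
      5.855
     ],
     "position": [
      -0.56,
      0.753
     ],
     "objective": 6.192,
     "d_checked": true
    },
    "P9": {
     "D": [
      5.365,
      0.221
     ],
     "position": [
      2.372,
      -2.535
     ],
     "objective": 15.67,
     "d_checked": true
    },
    "P10": {
     "D": [
      4.021,
      1.721
     ],
     "position": [
      1.588,
      -1.659
     ],
     "objective": 7.447,
     "d_checked": true
    }
   }
  },
  {
   "t": 3,
   "l": -1.0,
   "prey": [
    -0.454,
    -2.43
   ],
   "prey_checked": true,
   "cells": {
    "P1": {
     "D": [
      1.586,
      0.931
     ],
     "position": [
      -0.619,
      -2.527
     ],
     "objective": -3.142,
     "d_checked": true
    },
    "P2": {
     "D": [
      0.18,
      0.308
     ],
     "position": [
      -0.472,
      -2.462
     ],
     "objective": -2.671,
     "d_checked": true
    },
    "P3": {
     "D": [
      0.637,
      0.673
     ],
     "position": [
      -0.52,
      -2.5
     ],
     "objective": -2.82,
     "d_checked": true
    },
    "P4": {
     "D": [
      0.224,
      0.181
     ],
     "position": [
      -0.477,
      -2.449
     ],
     "objective": -2.693,
     "d_checked": false
    },
    "P5": {
     "D": [
      1.225,
      1.952
     ],
     "position": [
      -0.582,
      -2.634
     ],
     "objective": -2.955,
     "d_checked": true
    },
    "P6": {
     "D": [
      0.124,
      0.181
     ],
     "position": [
      -0.467,
      -2.449
     ],
     "objective": -2.657,
     "d_checked": true
    },
    "P7": {
     "D": [
      0.044,
      0.128
     ],
     "position": [
      -0.458,
      -2.443
     ],
     "objective": -2.63,
     "d_checked": true
    },
    "P8": {
     "D": [
      0.107,
      3.183
     ],
     "position": [
      -0.465,
      -2.762
     ],
     "objective": -2.416,
     "d_checked": true
    },
    "P9": {
     "D": [
      2.826,
      0.105
     ],
     "position": [
      -0.749,
      -2.441
     ],
     "objective": -3.57,
     "d_checked": true
    },
    "P10": {
     "D": [
      2.042,
      0.771
     ],
     "position": [
      -0.667,
      -2.511
     ],
     "objective": -3.302,
     "d_checked": true
    }
   }
  }
 ],
 "final_prey": {
  "prey": [
   -0.678,
   -1.87
  ],
  "prey_checked": false
 },
 "best_after": {
  "P1": {
   "position": [
    -0.619,
    -2.527
   ],
   "objective": -3.142
  },
  "P2": {
   "position": [
    -0.472,
    -2.462
   ],
   "objective": -2.671
  },
  "P3": {
   "position": [
    -0.52,
    -2.5
   ],
   "objective": -2.82
  },
  "P4": {
   "position": [
    -0.678,
    -2.617
   ],
   "objective": -3.292
  },
  "P5": {
   "position": [
    -0.582,
    -2.634
   ],
   "objective": -2.955
  },
  "P6": {
   "position": [
    -1.493,
    -2.573
   ],
   "objective": -5.27
  },
  "P7": {
   "position": [
    -0.458,
    -2.443
   ],
   "objective": -2.63
  },
  "P8": {
   "position": [
    -0.465,
    -2.762
   ],
   "objective": -2.416
  },
  "P9": {
   "position": [
    -0.749,
    -2.441
   ],
   "objective": -3.57
  },
  "P10": {
   "position": [
    -0.667,
    -2.511
   ],
   "objective": -3.302
  }
 }
}
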