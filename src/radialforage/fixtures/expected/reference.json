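{
 "example4_distance": 2.236759,
 "example1_relmin_q_k3": 5.0,
 "animal1_d_1_14": 3.1942,
 "lmrft_animal1_level4_first_targets": [
  16,
  7,
  17,
  8,
  18
 ],
 "lmrft_animal1_level4_first_scores": [
  1.4707,
  1.7417
 ],
 "lmrft_paths": {
  "1": {
   "2": [
    6,
    4,
    10,
    11,
    16,
    14,
    1,
    7,
    8,
    9,
    3,
    5,
    18,
    13
   ],
   "3": [
    16,
    14,
    4,
    7,
    17,
    3,
    18,
    8,
    2,
    6,
    19,
    11,
    20,
    15
   ],
   "4": [
    16,
    7,
    17,
    8,
    18,
    3,
    4,
    6,
    14,
    11,
    15,
    20,
    13,
    5
   ],
   "5": [
    7,
    17,
    18,
    8,
    4,
    14,
    3,
    6,
    11,
    20,
    15,
    13,
    5,
    16
   ]
  },
  "2": {
   "2": [
    13,
    1,
    9,
    6,
    12,
    15,
    10,
    16,
    11,
    3,
    5,
    2,
    4,
    8
   ],
   "3": [
    6,
    15,
    16,
    18,
    19,
    1,
    14,
    17,
    10,
    5,
    3,
    2,
    9,
    4
   ],
   "4": [
    16,
    6,
    15,
    1,
    10,
    5,
    18,
    14,
    2,
    3,
    4,
    11,
    7,
    8
   ],
   "5": [
    1,
    10,
    16,
    15,
    6,
    14,
    18,
    8,
    3,
    11,
    5,
    4,
    19,
    2
   ]
  },
  "3": {
   "2": [
    14,
    1,
    6,
    7,
    5,
    3,
    15,
    2,
    8,
    11,
    12,
    9,
    13,
    16
   ],
   "3": [
    16,
    3,
    6,
    15,
    5,
    9,
    13,
    18,
    19,
    11,
    1,
    7,
    2,
    14
   ],
   "4": [
    6,
    5,
    13,
    18,
    11,
    9,
    15,
    1,
    7,
    3,
    2,
    8,
    19,
    16
   ],
   "5": [
    5,
    6,
    13,
    11,
    9,
    15,
    7,
    3,
    14,
    16,
    1,
    19,
    2,
    18
   ]
  }
 },
 "grid_lmrft": {
  "1": {
   "2": 22.917,
   "3": 21.229,
   "4": 22.335,
   "5": 22.025
  },
  "2": {
   "2": 21.025,
   "3": 21.023,
   "4": 21.993,
   "5": 22.655
  },
  "3": {
   "2": 18.792,
   "3": 19.23,
   "4": 18.556,
   "5": 18.006
  }
 },
 "grid_smrft": {
  "1": {
   "2": 19.952,
   "3": 19.48,
   "4": 19.623,
   "5": 19.253
  },
  "2": {
   "2": 19.443,
   "3": 18.364,
   "4": 17.977,
   "5": 17.765
  },
  "3": {
   "2": 16.582,
   "3": 15.758,
   "4": 16.411,
   "5": 16.388
  }
 },
 "stated_levels_lmrft": {
  "1": 3,
  "2": 2,
  "3": 5
 },
 "stated_levels_smrft": {
  "1": 5,
  "2": 5,
  "3": 2
 }
}
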