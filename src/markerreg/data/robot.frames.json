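{
 "schema_version": 1,
 "frames": [
  {
   "segment": "pelvis",
   "origin": [
    "RASI",
    "LASI"
   ],
   "primary": {
    "start": [
     "LASI"
    ],
    "end": [
     "RASI"
    ],
    "axis": "z"
   },
   "secondary": {
    "start": [
     "RPSI",
     "LPSI"
    ],
    "end": [
     "RASI",
     "LASI"
    ],
    "axis": "x"
   }
  },
  {
   "segment": "femur_r",
   "origin": [
    "RKNM",
    "RKNL"
   ],
   "primary": {
    "start": [
     "RKNM"
    ],
    "end": [
     "RKNL"
    ],
    "axis": "z"
   },
   "secondary": {
    "start": [
     "RKNM",
     "RKNL"
    ],
    "end": [
     "RTHI"
    ],
    "axis": "y"
   }
  },
  {
   "segment": "tibia_r",
   "origin": [
    "RANM",
    "RANL"
   ],
   "primary": {
    "start": [
     "RANM"
    ],
    "end": [
     "RANL"
    ],
    "axis": "z"
   },
   "secondary": {
    "start": [
     "RANM",
     "RANL"
    ],
    "end": [
     "RTIB"
    ],
    "axis": "y"
   }
  },
  {
   "segment": "foot_r",
   "origin": [
    "RHEE"
   ],
   "primary": {
    "start": [
     "RHEE"
    ],
    "end": [
     "RTOE"
    ],
    "axis": "x"
   },
   "secondary": {
    "start": [
     "RTOE"
    ],
    "end": [
     "RMT5"
    ],
    "axis": "z"
   }
  },
  {
   "segment": "femur_l",
   "origin": [
    "LKNM",
    "LKNL"
   ],
   "primary": {
    "start": [
     "LKNL"
    ],
    "end": [
     "LKNM"
    ],
    "axis": "z"
   },
   "secondary": {
    "start": [
     "LKNM",
     "LKNL"
    ],
    "end": [
     "LTHI"
    ],
    "axis": "y"
   }
  },
  {
   "segment": "tibia_l",
   "origin": [
    "LANM",
    "LANL"
   ],
   "primary": {
    "start": [
     "LANL"
    ],
    "end": [
     "LANM"
    ],
    "axis": "z"
   },
   "secondary": {
    "start": [
     "LANM",
     "LANL"
    ],
    "end": [
     "LTIB"
    ],
    "axis": "y"
   }
  },
  {
   "segment": "foot_l",
   "origin": [
    "LHEE"
   ],
   "primary": {
    "start": [
     "LHEE"
    ],
    "end": [
     "LTOE"
    ],
    "axis": "x"
   },
   "secondary": {
    "start": [
     "LMT5"
    ],
    "end": [
     "LTOE"
    ],
    "axis": "z"
   }
  }
 ]
}
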