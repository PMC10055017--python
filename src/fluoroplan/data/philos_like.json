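{
 "name": "philos-like synthetic fixture",
 "version": "1",
 "marker": {
  "holes": [
   {
    "id": "H1",
    "center": [
     0.0,
     0.0,
     0.0
    ],
    "axis": [
     0.0,
     0.0,
     1.0
    ],
    "radius": 2.5,
    "depth": 4.0
   },
   {
    "id": "H2",
    "center": [
     25.0,
     0.0,
     0.0
    ],
    "axis": [
     0.0,
     0.0,
     1.0
    ],
    "radius": 2.5,
    "depth": 4.0
   },
   {
    "id": "H3",
    "center": [
     0.0,
     20.0,
     0.0
    ],
    "axis": [
     0.0,
     0.0,
     1.0
    ],
    "radius": 2.5,
    "depth": 4.0
   }
  ]
 },
 "implant": {
  "screws": [
   {
    "label": "A1",
    "seat": [
     -4.0,
     14.0,
     0.0
    ],
    "direction": [
     -0.05989229072794672,
     -0.27949735673041803,
     0.9582766516471475
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "A2",
    "seat": [
     0.0,
     16.0,
     0.0
    ],
    "direction": [
     0.01999600119960014,
     -0.27994401679440195,
     0.9598080575808068
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "A3",
    "seat": [
     4.0,
     14.0,
     0.0
    ],
    "direction": [
     0.09950371902099892,
     -0.278610413258797,
     0.9552357026015896
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "B4",
    "seat": [
     -3.5,
     9.0,
     0.0
    ],
    "direction": [
     -0.12038585308576921,
     -0.24077170617153842,
     0.9630868246861537
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "B5",
    "seat": [
     3.5,
     9.0,
     0.0
    ],
    "direction": [
     0.15961737689352443,
     -0.23942606534028665,
     0.9577042613611466
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "C6",
    "seat": [
     0.0,
     4.5,
     0.0
    ],
    "direction": [
     0.1428274026376352,
     -0.1428274026376352,
     0.979387903800927
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "D7",
    "seat": [
     0.0,
     0.0,
     0.0
    ],
    "direction": [
     0.0,
     0.0,
     1.0
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": true
   },
   {
    "label": "E8",
    "seat": [
     -3.0,
     -5.0,
     0.0
    ],
    "direction": [
     -0.10360608425945601,
     0.0,
     0.9946184088907778
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   },
   {
    "label": "E9",
    "seat": [
     3.0,
     -5.0,
     0.0
    ],
    "direction": [
     0.14430689307172856,
     0.0,
     0.9895329810632816
    ],
    "lengths": [
     16.0,
     18.0,
     20.0,
     22.0,
     24.0,
     26.0,
     28.0,
     30.0,
     32.0,
     34.0,
     36.0,
     38.0,
     40.0,
     42.0,
     44.0,
     46.0,
     48.0,
     50.0,
     52.0,
     54.0,
     56.0,
     58.0,
     60.0
    ],
    "central": false
   }
  ],
  "clip_to_plate": {
   "rotation": [
    [
     1.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.9975640502598242,
     -0.0697564737441253
    ],
    [
     0.0,
     0.0697564737441253,
     0.9975640502598242
    ]
   ],
   "translation": [
    -4.0,
    3.948309365355157,
    -27.792280459786827
   ]
  },
  "plate_axes": {
   "dv": [
    1.0,
    0.0,
    0.0
   ],
   "cc": [
    0.0,
    1.0,
    0.0
   ]
  }
 }
}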