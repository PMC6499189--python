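{
 "network": {
  "M": 4,
  "N": 4,
  "entries": [
   [
    0,
    0,
    0.5
   ],
   [
    0,
    2,
    0.25
   ],
   [
    2,
    1,
    0.1
   ],
   [
    2,
    2,
    0.2
   ],
   [
    2,
    3,
    0.3
   ],
   [
    3,
    0,
    0.4
   ]
  ]
 },
 "stores": {
  "crossbar": {
   "format": "crossbar",
   "WT": [
    [
     0.5,
     null,
     0.25,
     null
    ],
    [
     null,
     null,
     null,
     null
    ],
    [
     null,
     0.1,
     0.2,
     0.3
    ],
    [
     0.4,
     null,
     null,
     null
    ]
   ]
  },
  "csr": {
   "format": "csr",
   "PT": [
    0,
    2,
    2,
    5,
    6
   ],
   "WT": [
    [
     0,
     0.5
    ],
    [
     2,
     0.25
    ],
    [
     1,
     0.1
    ],
    [
     2,
     0.2
    ],
    [
     3,
     0.3
    ],
    [
     0,
     0.4
    ]
   ]
  },
  "rle": {
   "format": "rle",
   "PT": [
    0,
    3,
    3,
    7
   ],
   "WT": [
    [
     0,
     0.5
    ],
    [
     1,
     1
    ],
    [
     0,
     0.25
    ],
    [
     1,
     1
    ],
    [
     0,
     0.1
    ],
    [
     0,
     0.2
    ],
    [
     0,
     0.3
    ],
    [
     0,
     0.4
    ]
   ]
  },
  "bmp": {
   "format": "bmp",
   "AT": [
    "1010",
    "0000",
    "0111",
    "1000"
   ],
   "PT": [
    0,
    2,
    2,
    5
   ],
   "WT": [
    0.5,
    0.25,
    0.1,
    0.2,
    0.3,
    0.4
   ]
  }
 }
}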