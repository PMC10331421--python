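{
  "cell_size_m": 1.0,
  "destinations": {
    "dining": [
      5,
      23
    ],
    "lounge": [
      5,
      1
    ],
    "room_a1": [
      2,
      4
    ],
    "room_a2": [
      2,
      12
    ],
    "room_a3": [
      2,
      20
    ],
    "room_b1": [
      8,
      4
    ],
    "room_b2": [
      8,
      12
    ],
    "room_b3": [
      8,
      20
    ]
  },
  "nurse_stations": [
    [
      5,
      8
    ],
    [
      5,
      16
    ]
  ]
}
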