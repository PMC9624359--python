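{
 "animal": "a1",
 "mode": "observed",
 "level": null,
 "start": null,
 "labels": [
  7,
  9,
  10,
  12,
  17,
  5,
  1,
  19,
  8,
  16,
  18,
  13,
  2,
  6
 ],
 "legs": [
  5.3838,
  14.3692,
  18.8127,
  13.5455,
  8.3937,
  4.3913,
  9.3487,
  2.6456,
  4.3443,
  4.4099,
  7.6825,
  2.9215,
  6.0589
 ],
 "scores": null
}
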