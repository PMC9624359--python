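{
 "animal": "a3",
 "mode": "observed",
 "level": null,
 "start": null,
 "labels": [
  6,
  12,
  1,
  2,
  17,
  15,
  10,
  9,
  11,
  16,
  5,
  19,
  20,
  4
 ],
 "legs": [
  8.3994,
  3.5964,
  4.8556,
  10.1304,
  4.2725,
  9.6519,
  14.3692,
  5.9103,
  2.9805,
  1.1263,
  5.1823,
  8.8792,
  7.6126
 ],
 "scores": null
}
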