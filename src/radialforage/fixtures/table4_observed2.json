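{
 "animal": "a2",
 "mode": "observed",
 "level": null,
 "start": null,
 "labels": [
  11,
  2,
  10,
  12,
  7,
  6,
  20,
  19,
  18,
  16,
  8,
  1,
  13,
  3
 ],
 "legs": [
  6.0524,
  15.8547,
  18.8127,
  10.2036,
  2.9698,
  3.9776,
  8.8792,
  5.2476,
  4.4099,
  4.3443,
  8.524,
  2.068,
  1.472
 ],
 "scores": null
}
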