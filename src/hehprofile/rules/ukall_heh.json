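{
 "version": "1.0",
 "description": "UKALL-HeH risk decision table: class of each combination of whole-chromosome gains of 5, 17, 18 and 20. Good risk requires +17 and/or +18 in the absence of the +5/+20 combination.",
 "key_order": [
  "gain5",
  "gain17",
  "gain18",
  "gain20"
 ],
 "table": {
  "0,0,0,0": "PR",
  "0,0,0,1": "PR",
  "0,0,1,0": "GR",
  "0,0,1,1": "GR",
  "0,1,0,0": "GR",
  "0,1,0,1": "GR",
  "0,1,1,0": "GR",
  "0,1,1,1": "GR",
  "1,0,0,0": "PR",
  "1,0,0,1": "PR",
  "1,0,1,0": "GR",
  "1,0,1,1": "PR",
  "1,1,0,0": "GR",
  "1,1,0,1": "PR",
  "1,1,1,0": "GR",
  "1,1,1,1": "PR"
 }
}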