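{
 "percentiles": [
  {
   "tau": 0.25,
   "b0": 34.43,
   "b_bmi": 0.6878,
   "b_age": 0.03358,
   "b_t": -1.020,
   "b_t2": 0.04580,
   "b_t3": -0.00055,
   "b_bmi_t": -0.00725,
   "b_age_t": 0.001608
  },
  {
   "tau": 0.50,
   "b0": 36.71,
   "b_bmi": 0.7308,
   "b_age": 0.02551,
   "b_t": -0.906,
   "b_t2": 0.04298,
   "b_t3": -0.00052,
   "b_bmi_t": -0.00527,
   "b_age_t": 0.001542
  },
  {
   "tau": 0.75,
   "b0": 39.11,
   "b_bmi": 0.7839,
   "b_age": 0.02443,
   "b_t": -0.790,
   "b_t2": 0.03937,
   "b_t3": -0.00048,
   "b_bmi_t": -0.00399,
   "b_age_t": 0.000927
  }
 ],
 "bmi_range": [35, 95],
 "age_range": [18, 74],
 "time_range": [0, 36]
}
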