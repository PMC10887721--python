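# Canonical simulation scenarios: 3 ordered socioeconomic groups x 4 age bands.
#
# The base person-year grid (12-cell mean 2417, SD 1084) and base true-rate
# grid (mean 0.0003, SD 0.0002) were fixed once by least-squares so that the
# cell-wise expected counts n*lambda also have mean 0.8 and SD 0.784, with
# rates increasing in age and in socioeconomic rank and person-years
# decreasing in age.  Each scenario scales the two base grids by powers of 10.
#
# Age-band weights are the WHO World Standard population collapsed to four
# bands (0-24, 25-49, 50-69, 70+), in percent; they are renormalized to sum
# to 1 on load.

weights: [42.84, 35.32, 16.60, 5.27]

age_bands: ["0-24", "25-49", "50-69", "70+"]
group_labels: ["SES-1", "SES-2", "SES-3"]

base_person_years:
  - [2304, 2188, 2112, 1588]
  - [1628, 1547, 1493, 1122]
  - [4224, 4012, 3872, 2911]

base_rates:
  - [0.000082, 0.000121, 0.000245, 0.000257]
  - [0.000114, 0.000169, 0.000341, 0.000358]
  - [0.000222, 0.000329, 0.000664, 0.000699]

# person-year and rate multipliers per scenario id
scenarios:
  1: {py_scale: 1,   rate_scale: 1}
  2: {py_scale: 1,   rate_scale: 10}
  3: {py_scale: 10,  rate_scale: 1}
  4: {py_scale: 1,   rate_scale: 100}
  5: {py_scale: 10,  rate_scale: 10}
  6: {py_scale: 100, rate_scale: 1}
  7: {py_scale: 10,  rate_scale: 100}
  8: {py_scale: 100, rate_scale: 10}
  9: {py_scale: 100, rate_scale: 100}
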