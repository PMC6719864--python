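{
  "source": "NIST/CIAAW standard atomic weights and isotopic compositions (representative isotopic composition column)",
  "retrieved": "2026-09-30",
  "comment": "Fractional natural abundances. Te from the 8 stable isotopes; Xe from the 9 naturally occurring isotopes. Values sum to 1 per element to table precision.",
  "abundances": {
    "Te": {
      "120": 0.0009,
      "122": 0.0255,
      "123": 0.0089,
      "124": 0.0474,
      "125": 0.0707,
      "126": 0.1884,
      "128": 0.3174,
      "130": 0.3408
    },
    "Xe": {
      "124": 0.000952,
      "126": 0.000890,
      "128": 0.019102,
      "129": 0.264006,
      "130": 0.040710,
      "131": 0.212324,
      "132": 0.269086,
      "134": 0.104357,
      "136": 0.088573
    }
  }
}
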