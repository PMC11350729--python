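{
  "config_hash": null,
  "results": {
    "mechanism": {
      "classification": "conformational-step",
      "delta_aicc": 495.25069507953435,
      "hyperbolic": {
        "aicc": -460.6959645547946,
        "model": "hyperbolic",
        "n_points": 7,
        "params": {
          "KD1": 9.999999999999998,
          "k-conf": 1.9999999999999993,
          "kconf": 40.0
        },
        "ssr": 3.3526588471893e-30,
        "stderr": {
          "KD1": 1.6426223845956883e-15,
          "k-conf": 8.551874539958621e-16,
          "kconf": 1.7242448190974012e-15
        },
        "warnings": []
      },
      "linear": {
        "aicc": 34.554730524739725,
        "model": "linear",
        "n_points": 7,
        "params": {
          "k-1": 8.549147520860192,
          "k1": 0.7434873829524958
        },
        "ssr": 131.93379239851058,
        "stderr": {
          "k-1": 2.5346423688527278,
          "k1": 0.14529491768300273
        },
        "warnings": []
      },
      "note": "a nonlinear kobs([S]) identifies a conformational step but cannot distinguish induced fit from conformational selection",
      "selected_model": "hyperbolic",
      "threshold": 2.0
    }
  },
  "software": {
    "name": "hisfkin",
    "version": "0.1.0"
  }
}
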