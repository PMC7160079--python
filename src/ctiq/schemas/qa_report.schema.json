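{
 "$defs": {
  "DoseMatchSection": {
   "properties": {
    "base_dose": {
     "title": "Base Dose",
     "type": "number"
    },
    "doses": {
     "items": {
      "type": "number"
     },
     "title": "Doses",
     "type": "array"
    },
    "matched_dose": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Matched Dose"
    },
    "percent_increase": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Percent Increase"
    },
    "reached": {
     "title": "Reached",
     "type": "boolean"
    },
    "reference_score": {
     "title": "Reference Score",
     "type": "number"
    },
    "scores": {
     "items": {
      "type": "number"
     },
     "title": "Scores",
     "type": "array"
    }
   },
   "required": [
    "doses",
    "scores",
    "reference_score",
    "base_dose",
    "matched_dose",
    "percent_increase",
    "reached"
   ],
   "title": "DoseMatchSection",
   "type": "object"
  },
  "HUCheck": {
   "properties": {
    "hi": {
     "title": "Hi",
     "type": "number"
    },
    "lo": {
     "title": "Lo",
     "type": "number"
    },
    "passed": {
     "title": "Passed",
     "type": "boolean"
    },
    "value": {
     "title": "Value",
     "type": "number"
    }
   },
   "required": [
    "value",
    "lo",
    "hi",
    "passed"
   ],
   "title": "HUCheck",
   "type": "object"
  },
  "HUSection": {
   "properties": {
    "all_passed": {
     "title": "All Passed",
     "type": "boolean"
    },
    "materials": {
     "additionalProperties": {
      "$ref": "#/$defs/HUCheck"
     },
     "title": "Materials",
     "type": "object"
    }
   },
   "required": [
    "materials",
    "all_passed"
   ],
   "title": "HUSection",
   "type": "object"
  },
  "LowContrastSection": {
   "properties": {
    "counts": {
     "additionalProperties": {
      "type": "integer"
     },
     "title": "Counts",
     "type": "object"
    },
    "rule_threshold": {
     "title": "Rule Threshold",
     "type": "number"
    },
    "score": {
     "title": "Score",
     "type": "integer"
    }
   },
   "required": [
    "counts",
    "score",
    "rule_threshold"
   ],
   "title": "LowContrastSection",
   "type": "object"
  },
  "MTFSection": {
   "properties": {
    "curve_csv": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Curve Csv"
    },
    "f10": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "F10"
    },
    "f2": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "F2"
    },
    "f50": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "F50"
    },
    "f90": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "F90"
    }
   },
   "title": "MTFSection",
   "type": "object"
  },
  "NPSSection": {
   "properties": {
    "curve_csv": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Curve Csv"
    },
    "mode": {
     "title": "Mode",
     "type": "string"
    },
    "n_rois": {
     "title": "N Rois",
     "type": "integer"
    },
    "noise_sd": {
     "title": "Noise Sd",
     "type": "number"
    },
    "peak_frequency": {
     "title": "Peak Frequency",
     "type": "number"
    }
   },
   "required": [
    "noise_sd",
    "peak_frequency",
    "n_rois",
    "mode"
   ],
   "title": "NPSSection",
   "type": "object"
  },
  "Provenance": {
   "properties": {
    "config": {
     "additionalProperties": true,
     "title": "Config",
     "type": "object"
    },
    "inputs": {
     "additionalProperties": {
      "type": "string"
     },
     "default": {},
     "title": "Inputs",
     "type": "object"
    },
    "seed": {
     "title": "Seed",
     "type": "integer"
    },
    "software": {
     "default": "ctiq",
     "title": "Software",
     "type": "string"
    },
    "version": {
     "default": "0.1.0",
     "title": "Version",
     "type": "string"
    }
   },
   "required": [
    "seed",
    "config"
   ],
   "title": "Provenance",
   "type": "object"
  },
  "SSPSection": {
   "properties": {
    "curve_csv": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Curve Csv"
    },
    "fwhm_mm": {
     "title": "Fwhm Mm",
     "type": "number"
    }
   },
   "required": [
    "fwhm_mm"
   ],
   "title": "SSPSection",
   "type": "object"
  },
  "UniformitySection": {
   "properties": {
    "centre_mean": {
     "title": "Centre Mean",
     "type": "number"
    },
    "diffs": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Diffs",
     "type": "object"
    },
    "limit": {
     "title": "Limit",
     "type": "number"
    },
    "passed": {
     "title": "Passed",
     "type": "boolean"
    },
    "peripheral_means": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Peripheral Means",
     "type": "object"
    }
   },
   "required": [
    "centre_mean",
    "peripheral_means",
    "diffs",
    "limit",
    "passed"
   ],
   "title": "UniformitySection",
   "type": "object"
  }
 },
 "properties": {
  "dose_match": {
   "anyOf": [
    {
     "$ref": "#/$defs/DoseMatchSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "hu": {
   "anyOf": [
    {
     "$ref": "#/$defs/HUSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "lowcontrast": {
   "anyOf": [
    {
     "$ref": "#/$defs/LowContrastSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "mtf_edge": {
   "anyOf": [
    {
     "$ref": "#/$defs/MTFSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "mtf_wire": {
   "anyOf": [
    {
     "$ref": "#/$defs/MTFSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "nps": {
   "anyOf": [
    {
     "$ref": "#/$defs/NPSSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "provenance": {
   "$ref": "#/$defs/Provenance"
  },
  "ssp": {
   "anyOf": [
    {
     "$ref": "#/$defs/SSPSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "uniformity": {
   "anyOf": [
    {
     "$ref": "#/$defs/UniformitySection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  }
 },
 "required": [
  "provenance"
 ],
 "title": "QAReport",
 "type": "object"
}
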