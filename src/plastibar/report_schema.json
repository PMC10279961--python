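{
  "required": {
    "tool": "string",
    "version": "string",
    "config": "object",
    "config_hash": "string",
    "stages": {
      "type": "object",
      "required": {
        "scan": {
          "type": "object",
          "required": {
            "alignment_length": "number",
            "n_samples": "number",
            "site_classes": "object",
            "windows": "array"
          }
        },
        "mine": {
          "type": "object",
          "required": {
            "rejection_tally": "object",
            "candidates": "array"
          }
        },
        "discriminate": {
          "type": "object",
          "required": {
            "regions": "array"
          }
        }
      }
    }
  }
}
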