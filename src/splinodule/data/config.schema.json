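{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "splinodule pipeline configuration",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "denoise": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "enabled": {"type": "boolean", "default": true},
        "family": {"enum": ["haar", "semiorthogonal_bspline", "biorthogonal_spline"], "default": "biorthogonal_spline"},
        "degree": {"type": "integer", "minimum": 0, "default": 3},
        "dual_order": {"type": "integer", "minimum": 1, "default": 2},
        "levels": {"type": "integer", "minimum": 1, "default": 3},
        "mode": {"enum": ["hard", "soft", "semisoft", "stein"], "default": "soft"},
        "threshold_policy": {"enum": ["global", "per_level"], "default": "per_level"},
        "threshold": {"type": ["number", "null"], "exclusiveMinimum": 0, "default": null,
                      "description": "fixed shrinkage threshold; null selects the universal threshold"}
      }
    },
    "compress": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "enabled": {"type": "boolean", "default": false},
        "family": {"enum": ["haar", "biorthogonal_spline"], "default": "biorthogonal_spline"},
        "degree": {"type": "integer", "minimum": 0, "default": 1},
        "dual_order": {"type": "integer", "minimum": 1, "default": 2},
        "levels": {"type": "integer", "minimum": 1, "default": 4},
        "ratio": {"type": "number", "minimum": 1, "default": 10.0,
                  "description": "target coefficient-count compression ratio"},
        "quantization_step": {"type": "number", "minimum": 0, "default": 0.0}
      }
    },
    "detect": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "levels": {"type": "integer", "minimum": 2, "default": 4},
        "response_threshold_k": {"type": "number", "exclusiveMinimum": 0, "default": 3.5,
                                 "description": "local-maximum threshold in multiples of the per-level robust scale"},
        "min_circularity": {"type": "number", "default": 0.6},
        "max_aspect_ratio": {"type": "number", "minimum": 1, "default": 2.5},
        "min_convexity": {"type": "number", "default": 0.8},
        "min_area": {"type": "number", "minimum": 0, "default": 20},
        "max_area": {"type": "number", "default": 2000},
        "max_coherence": {"type": "number", "default": 0.3,
                          "description": "structure-tensor coherence gate; vessels are coherent, nodules are not"},
        "min_persistence": {"type": "integer", "minimum": 1, "default": 2},
        "match_radius": {"type": "number", "exclusiveMinimum": 0, "default": 5.0},
        "reject_boundary_touching": {"type": "boolean", "default": true},
        "boundary": {"enum": ["symmetric", "periodic"], "default": "symmetric"}
      }
    },
    "io": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "bit_depth": {"enum": [8, 16], "default": 8},
        "output_dir": {"type": "string", "default": "."}
      }
    },
    "detect_family": {"enum": ["haar", "semiorthogonal_bspline", "biorthogonal_spline"], "default": "biorthogonal_spline"},
    "detect_degree": {"type": "integer", "minimum": 0, "default": 3},
    "detect_dual_order": {"type": "integer", "minimum": 1, "default": 2},
    "seed": {"type": "integer", "default": 0}
  }
}
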