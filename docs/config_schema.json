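{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "imputequal benchmark RunConfig",
  "description": "Schema of the YAML configuration accepted by `imputequal benchmark` / imputequal.RunConfig.from_yaml. Exactly one of csv_path or synthetic must be given.",
  "type": "object",
  "additionalProperties": false,
  "required": ["output_dir"],
  "properties": {
    "output_dir": {"type": "string", "description": "Directory for metrics.csv and manifest.json."},
    "csv_path": {"type": ["string", "null"], "description": "Complete ground-truth dataset CSV (with schema sidecar)."},
    "schema_path": {"type": ["string", "null"], "description": "Schema sidecar path; defaults to <csv_path>.schema.json."},
    "synthetic": {
      "type": ["object", "null"],
      "description": "Keyword arguments for the synthetic generators; 'kind' selects numeric|mixed, remaining keys are passed through (n, d_informative, class_sep, seed, ...).",
      "properties": {"kind": {"enum": ["numeric", "mixed"]}}
    },
    "rates": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}, "description": "MCAR missingness rates to scan."},
    "imputers": {
      "type": "object",
      "description": "Map imputer name -> parameter dict.",
      "propertyNames": {"enum": ["mean", "chained_equations"]}
    },
    "n_directions": {"type": ["integer", "null"], "description": "M random projection directions; null means 2d."},
    "n_partitions": {"type": "integer", "minimum": 1, "description": "P random half-partitions (default 10)."},
    "kl_bins": {"type": "integer", "minimum": 2, "description": "Histogram bins for KL (default 30)."},
    "outlier_threshold": {"type": "number", "minimum": 0, "description": "Threshold on w_hat for the outlier proportion."},
    "metrics": {"type": "array", "items": {"enum": ["A", "B", "C"]}, "description": "Discrepancy classes to compute."},
    "mask_seed": {"type": "integer"},
    "imputer_seed": {"type": "integer"},
    "projection_seed": {"type": "integer"}
  }
}
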