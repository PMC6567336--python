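# JSON report schema

`seapen.run_pipeline` returns (and `seapen.io.write_report` serialises with
sorted keys, so identical runs are byte-identical) a report with these
sections. Lengths are mm, weights g, areas m², densities colonies/m².

```
{
  "seed": int,
  "source": "synthetic" | "measured",
  "models": {
    "rachis_length":  {"slope_mm_per_leaf", "intercept_mm",
                       "rms_relative_error", "correlation", "n_fit"},
    "total_length":   {...same fields...},
    "fresh_weight_cubic":   {"coefficients_g": [c3, c2, c1, c0],
                             "rms_relative_error", "validity_min_n", "n_fit"},
    "fresh_weight_surface": {"coefficients": [a3, a2, a1, b1, a0],
                             "rms_relative_error", "n_fit"},
    "dry_weight": null | {"coefficients": [d3, d2, d1, d0],
                          "rms_relative_error", "n_fit"}
  },
  "moments": {
    "trawl": {"m", "mean", "sd_corrected", "sd_uncorrected",
              "skewness", "kurtosis"},          # null when undefined
    "rov":   {...}                              # only when ROV data present
  },
  "dispersion": [ {"leaf_count", "m", "mean_rachis_mm", "sd_rachis_mm"} ],
  "comparison": {                               # only when ROV data present
    "reference": "rov",
    "relative_mean_diff", "relative_skewness_diff",
    "histogram_trawl": {"<count>": frequency, ...},
    "histogram_rov":   {...}                    # shared bin range
  },
  "biomass": {                                  # only when ROV data present
    "m_observed", "mean_predicted_weight_g",
    "density_per_m2", "density_source",         # "config" | "trawl_count_over_area"
    "area_m2", "total_weight_g",
    "n_not_applicable", "fraction_not_applicable"
  },
  "validation": {                               # only when ROV data present
    "predicted_mean_g", "measured_mean_g", "relative_error"
  }
}
```

The invariant `total_weight_g == mean_predicted_weight_g * density_per_m2 *
area_m2` holds bit-exactly, and `relative_error` is signed:
`(predicted − measured) / measured`.
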