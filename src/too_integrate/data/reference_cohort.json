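{
  "description": "Reference 16-patient lung-specific CUP cohort: per-patient inter-tumor time lag, extrathoracic site, genomic-evidence category, per-lesion Methyl Scores, and the expected per-lesion labels from each analysis track.",
  "schema_version": "1.0",
  "patients": [
    {
      "id": "P1",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "colon_rectum",
      "earlier": null,
      "cgp_evidence": "shared_driver",
      "driver": "egfr_snv",
      "msi_extra": "MSS",
      "methyl": {"lung": 0.475, "extra": 0.378},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "M",
        "methyl_lung": "P", "methyl_extra": "M",
        "class": "I", "table_concordance": "Y"
      }
    },
    {
      "id": "P2",
      "time_lag": "metachronous",
      "interval_months": 8,
      "extra_site": "stomach",
      "earlier": "extra",
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.537, "extra": 0.634},
      "expected": {
        "cgp_lung": "M", "cgp_extra": "P",
        "methyl_lung": "M", "methyl_extra": "P",
        "class": "II", "table_concordance": "Y"
      }
    },
    {
      "id": "P3",
      "time_lag": "metachronous",
      "interval_months": 8,
      "extra_site": "stomach",
      "earlier": "lung",
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.393, "extra": 0.354},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "M",
        "methyl_lung": "P", "methyl_extra": "M",
        "class": "II", "table_concordance": "Y"
      }
    },
    {
      "id": "P4",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "colon_rectum",
      "earlier": null,
      "cgp_evidence": "shared_driver",
      "driver": "egfr_exon19del",
      "msi_extra": "MSS",
      "methyl": {"lung": 0.349, "extra": 0.391},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "M",
        "methyl_lung": "P", "methyl_extra": "M",
        "class": "I", "table_concordance": "Y"
      }
    },
    {
      "id": "P5",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "stomach",
      "earlier": null,
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.531, "extra": 0.72},
      "expected": {
        "cgp_lung": "Inconclusive", "cgp_extra": "Inconclusive",
        "methyl_lung": "M", "methyl_extra": "P",
        "class": "III", "table_concordance": null
      }
    },
    {
      "id": "P6",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "colon_rectum",
      "earlier": null,
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.297, "extra": 0.652},
      "expected": {
        "cgp_lung": "Inconclusive", "cgp_extra": "Inconclusive",
        "methyl_lung": "P", "methyl_extra": "P",
        "class": "III", "table_concordance": null
      }
    },
    {
      "id": "P7",
      "time_lag": "metachronous",
      "interval_months": 8,
      "extra_site": "cervix",
      "earlier": "extra",
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.695, "extra": 0.666},
      "expected": {
        "cgp_lung": "M", "cgp_extra": "P",
        "methyl_lung": "M", "methyl_extra": "P",
        "class": "II", "table_concordance": "Y"
      }
    },
    {
      "id": "P8",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "colon_rectum",
      "earlier": null,
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.575, "extra": 0.554},
      "expected": {
        "cgp_lung": "Inconclusive", "cgp_extra": "Inconclusive",
        "methyl_lung": "M", "methyl_extra": "P",
        "class": "III", "table_concordance": null
      }
    },
    {
      "id": "P9",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "colon_rectum",
      "earlier": null,
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.491, "extra": 0.455},
      "expected": {
        "cgp_lung": "Inconclusive", "cgp_extra": "Inconclusive",
        "methyl_lung": "P", "methyl_extra": "M",
        "class": "III", "table_concordance": null
      }
    },
    {
      "id": "P10",
      "time_lag": "metachronous",
      "interval_months": 8,
      "extra_site": "cervix",
      "earlier": "extra",
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.715, "extra": 0.713},
      "expected": {
        "cgp_lung": "M", "cgp_extra": "P",
        "methyl_lung": "M", "methyl_extra": "P",
        "class": "II", "table_concordance": "Y"
      }
    },
    {
      "id": "P11",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "stomach",
      "earlier": null,
      "cgp_evidence": "zero_shared",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": null, "extra": 0.751},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "P",
        "methyl_lung": null, "methyl_extra": "P",
        "class": "I", "table_concordance": "Y"
      }
    },
    {
      "id": "P12",
      "time_lag": "metachronous",
      "interval_months": 8,
      "extra_site": "colon_rectum",
      "earlier": "lung",
      "cgp_evidence": "zero_shared",
      "driver": null,
      "msi_extra": "MSI",
      "methyl": {"lung": 0.259, "extra": 0.647},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "P",
        "methyl_lung": "P", "methyl_extra": "P",
        "class": "I", "table_concordance": "Y"
      }
    },
    {
      "id": "P13",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "cervix",
      "earlier": null,
      "cgp_evidence": "zero_shared",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.289, "extra": 0.548},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "P",
        "methyl_lung": "P", "methyl_extra": "P",
        "class": "I", "table_concordance": "Y"
      }
    },
    {
      "id": "P14",
      "time_lag": "metachronous",
      "interval_months": 8,
      "extra_site": "colon_rectum",
      "earlier": "lung",
      "cgp_evidence": "zero_shared",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.249, "extra": 0.797},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "P",
        "methyl_lung": "P", "methyl_extra": "P",
        "class": "I", "table_concordance": "Y"
      }
    },
    {
      "id": "P15",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "stomach",
      "earlier": null,
      "cgp_evidence": "criteria_met",
      "driver": null,
      "msi_extra": "MSS",
      "methyl": {"lung": 0.428, "extra": 0.556},
      "expected": {
        "cgp_lung": "Inconclusive", "cgp_extra": "Inconclusive",
        "methyl_lung": "P", "methyl_extra": "P",
        "class": "III", "table_concordance": null
      }
    },
    {
      "id": "P16",
      "time_lag": "synchronous",
      "interval_months": 0,
      "extra_site": "cervix",
      "earlier": null,
      "cgp_evidence": "shared_driver",
      "driver": "alk_fusion",
      "msi_extra": "MSS",
      "methyl": {"lung": null, "extra": null},
      "expected": {
        "cgp_lung": "P", "cgp_extra": "M",
        "methyl_lung": null, "methyl_extra": null,
        "class": "I", "table_concordance": null
      }
    }
  ]
}
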