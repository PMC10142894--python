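{
  "comparison": {
    "alpha": 0.05,
    "groups": [
      "baseline_no_nod_trend",
      "not_forced_effect",
      "forced_effect"
    ],
    "interpretation": {
      "baseline_no_nod_trend": "arousal-decreasing",
      "forced_effect": "arousal-decreasing",
      "not_forced_effect": "arousal-increasing"
    },
    "kruskal_wallis": {
      "H": 12.366737494095334,
      "df": 2,
      "p": 0.002063464841816931
    },
    "mean_per_s": [
      8.270247851384302e-05,
      -0.0004488248413660567,
      0.0007334956743840652
    ],
    "n": [
      45,
      17,
      14
    ],
    "pairwise_lsd": [
      {
        "T": 2.441040509495993,
        "p": 0.01707041013687777,
        "pair": [
          "baseline_no_nod_trend",
          "not_forced_effect"
        ],
        "significant": true
      },
      {
        "T": 2.1889073092077878,
        "p": 0.03180218927882365,
        "pair": [
          "baseline_no_nod_trend",
          "forced_effect"
        ],
        "significant": true
      },
      {
        "T": 3.781573262715619,
        "p": 0.00031627083339058376,
        "pair": [
          "not_forced_effect",
          "forced_effect"
        ],
        "significant": true
      }
    ],
    "per_session_counts": {
      "baseline_no_nod_trend": {
        "no_nodding_video_00": 18,
        "no_nodding_video_01": 18,
        "with_video_not_forced_00": 4,
        "with_video_not_forced_01": 5
      },
      "forced_effect": {
        "with_video_forced_00": 7,
        "with_video_forced_01": 7
      },
      "not_forced_effect": {
        "with_video_not_forced_00": 9,
        "with_video_not_forced_01": 8
      }
    }
  },
  "config": {
    "alpha": 0.05,
    "artifact_rejection": true,
    "baseline_stride": 50,
    "omnibus_alpha": null,
    "out_dir": "golden",
    "seed": 20240901,
    "sessions": [],
    "simulate": {
      "groups": [
        {
          "condition": "no_nodding_video",
          "duration_s": 900.0,
          "nod_rate_per_min": 0.0
        },
        {
          "condition": "with_video_not_forced",
          "duration_s": 900.0,
          "effect_delta": -0.3,
          "nod_rate_per_min": 0.8
        },
        {
          "condition": "with_video_forced",
          "cue_period_s": 120.0,
          "duration_s": 900.0,
          "effect_delta": 0.3
        }
      ],
      "n_per_group": [
        2,
        2,
        2
      ]
    },
    "sleep_policy": "include",
    "t0_s": 60.0,
    "window_beats": 100
  },
  "seed": 20240901,
  "sessions": [
    {
      "condition": "no_nodding_video",
      "exclusions": [],
      "half": "second",
      "n_all_per_s": -2.004446552414181e-06,
      "n_baseline": 18,
      "n_beats": 1060,
      "n_nod_effects": 0,
      "n_nod_exclusions": 0,
      "n_nods": 0,
      "n_rejected_beats": 0,
      "session_id": "no_nodding_video_00"
    },
    {
      "condition": "no_nodding_video",
      "exclusions": [],
      "half": "second",
      "n_all_per_s": -8.03063398380472e-06,
      "n_baseline": 18,
      "n_beats": 1060,
      "n_nod_effects": 0,
      "n_nod_exclusions": 0,
      "n_nods": 0,
      "n_rejected_beats": 0,
      "session_id": "no_nodding_video_01"
    },
    {
      "condition": "with_video_not_forced",
      "exclusions": [
        {
          "reason": "before first valid pNN50 sample",
          "t": 37.335976861729264
        },
        {
          "reason": "before first valid pNN50 sample",
          "t": 55.62817661878943
        }
      ],
      "half": "second",
      "n_all_per_s": -8.407844119173281e-05,
      "n_baseline": 4,
      "n_beats": 1060,
      "n_nod_effects": 9,
      "n_nod_exclusions": 2,
      "n_nods": 11,
      "n_rejected_beats": 0,
      "session_id": "with_video_not_forced_00"
    },
    {
      "condition": "with_video_not_forced",
      "exclusions": [
        {
          "reason": "before first valid pNN50 sample",
          "t": 42.75053038539408
        },
        {
          "reason": "before first valid pNN50 sample",
          "t": 68.9682891407965
        },
        {
          "reason": "t + t0 beyond last valid pNN50 sample",
          "t": 875.409329828226
        }
      ],
      "half": "second",
      "n_all_per_s": 0.00010247393263065405,
      "n_baseline": 5,
      "n_beats": 1060,
      "n_nod_effects": 8,
      "n_nod_exclusions": 3,
      "n_nods": 11,
      "n_rejected_beats": 0,
      "session_id": "with_video_not_forced_01"
    },
    {
      "condition": "with_video_forced",
      "exclusions": [],
      "half": "second",
      "n_all_per_s": 8.335503188292347e-05,
      "n_baseline": 0,
      "n_beats": 1059,
      "n_nod_effects": 7,
      "n_nod_exclusions": 0,
      "n_nods": 7,
      "n_rejected_beats": 0,
      "session_id": "with_video_forced_00"
    },
    {
      "condition": "with_video_forced",
      "exclusions": [],
      "half": "second",
      "n_all_per_s": -1.111799168775598e-05,
      "n_baseline": 0,
      "n_beats": 1058,
      "n_nod_effects": 7,
      "n_nod_exclusions": 0,
      "n_nods": 7,
      "n_rejected_beats": 0,
      "session_id": "with_video_forced_01"
    }
  ],
  "version": "0.1.0"
}
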