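# Default synthetic cohort recipe: a two-group suspected-pulmonary-hypertension
# referral population (39 no-PH / 194 PH). Marginals are mean/sd of each metric
# per group with optional physiologic truncation bounds; corr_mpap is the target
# Pearson correlation of the metric with catheter mPAP inside the group.
# PVR carries no lower bound: a lower-truncated normal cannot reach mean/sd =
# 149/167 (no-PH), so the marginal is left unbounded for both groups.
version: 1
groups:
  NO_PH:
    n: 39
    mpap: {mean: 19.0, sd: 3.0, lower: 0.0, upper: 25.0}
    lge_rate: 0.064516   # 2/31
    metrics:
      pvr:                   {mean: 149.0, sd: 167.0, corr_mpap: 0.80}
      trjv:                  {mean: 2.6,   sd: 0.6,   corr_mpap: 0.70, lower: 0.0}
      echo_mpap:             {mean: 25.4,  sd: 7.6,   corr_mpap: 0.74, lower: 0.0}
      rvedvi:                {mean: 77.7,  sd: 24.6,  corr_mpap: 0.39, lower: 0.0}
      rv_mass_index:         {mean: 13.7,  sd: 6.92,  corr_mpap: 0.74, lower: 0.0}
      vmi:                   {mean: 0.26,  sd: 0.11,  corr_mpap: 0.78, lower: 0.0}
      rvef:                  {mean: 39.7,  sd: 14.5,  corr_mpap: -0.43, lower: 0.0, upper: 100.0}
      rvsvi:                 {mean: 31.4,  sd: 13.3,  corr_mpap: -0.24, lower: 0.0}
      tapse:                 {mean: 2.21,  sd: 0.66,  corr_mpap: -0.40}
      f_taad:                {mean: 24.6,  sd: 7.89,  corr_mpap: -0.53}
      sfd:                   {mean: 1.10,  sd: 0.45,  corr_mpap: -0.46}
      f_sfd:                 {mean: 27.1,  sd: 11.5,  corr_mpap: -0.55}
      rvrac:                 {mean: 39.8,  sd: 10.5,  corr_mpap: -0.59, upper: 100.0}
      sei:                   {mean: 1.19,  sd: 0.19,  corr_mpap: 0.71, lower: 0.0}
      dei:                   {mean: 1.17,  sd: 0.12,  corr_mpap: 0.45, lower: 0.0}
      pa_average_velocity:   {mean: 13.6,  sd: 6.7,   corr_mpap: -0.55, lower: 0.0}
      pa_retrograde_flow:    {mean: 0.2,   sd: 0.1,   corr_mpap: -0.33, lower: 0.0}
      pa_retrograde_percent: {mean: 9.3,   sd: 7.2,   corr_mpap: -0.34, lower: 0.0, upper: 100.0}
      pa_rac:                {mean: 17.8,  sd: 6.6,   corr_mpap: -0.54, lower: 0.0}
      pa_systolic_area:      {mean: 7.8,   sd: 4.6,   corr_mpap: 0.28, lower: 0.0}
      pa_diastolic_area:     {mean: 6.7,   sd: 4.7,   corr_mpap: 0.35, lower: 0.0}
  PH:
    n: 194
    mpap: {mean: 45.0, sd: 12.0, lower: 25.0}
    lge_rate: 0.84375   # 108/128
    metrics:
      pvr:                   {mean: 587.0, sd: 411.0, corr_mpap: 0.80}
      trjv:                  {mean: 3.9,   sd: 0.9,   corr_mpap: 0.70, lower: 0.0}
      echo_mpap:             {mean: 46.8,  sd: 16.6,  corr_mpap: 0.74, lower: 0.0}
      rvedvi:                {mean: 99.1,  sd: 39.0,  corr_mpap: 0.39, lower: 0.0}
      rv_mass_index:         {mean: 37.6,  sd: 18.7,  corr_mpap: 0.74, lower: 0.0}
      vmi:                   {mean: 0.70,  sd: 0.35,  corr_mpap: 0.78, lower: 0.0}
      rvef:                  {mean: 28.2,  sd: 14.5,  corr_mpap: -0.43, lower: 0.0, upper: 100.0}
      rvsvi:                 {mean: 23.3,  sd: 13.2,  corr_mpap: -0.24, lower: 0.0}
      tapse:                 {mean: 1.55,  sd: 0.76,  corr_mpap: -0.40}
      f_taad:                {mean: 15.9,  sd: 7.49,  corr_mpap: -0.53}
      sfd:                   {mean: 0.64,  sd: 0.52,  corr_mpap: -0.46}
      f_sfd:                 {mean: 14.4,  sd: 12.3,  corr_mpap: -0.55}
      rvrac:                 {mean: 26.2,  sd: 13.4,  corr_mpap: -0.59, upper: 100.0}
      sei:                   {mean: 1.57,  sd: 0.52,  corr_mpap: 0.71, lower: 0.0}
      dei:                   {mean: 1.28,  sd: 0.23,  corr_mpap: 0.45, lower: 0.0}
      pa_average_velocity:   {mean: 7.6,   sd: 3.4,   corr_mpap: -0.55, lower: 0.0}
      pa_retrograde_flow:    {mean: 0.5,   sd: 0.3,   corr_mpap: -0.33, lower: 0.0}
      pa_retrograde_percent: {mean: 16.3,  sd: 9.2,   corr_mpap: -0.34, lower: 0.0, upper: 100.0}
      pa_rac:                {mean: 8.1,   sd: 6.5,   corr_mpap: -0.54, lower: 0.0}
      pa_systolic_area:      {mean: 9.7,   sd: 2.8,   corr_mpap: 0.28, lower: 0.0}
      pa_diastolic_area:     {mean: 8.9,   sd: 2.8,   corr_mpap: 0.35, lower: 0.0}
# PH aetiology mix (apportioned to the PH group size by largest remainder).
subgroup_counts:
  IPAH: 28
  PAH_CTD: 39
  PAH_OTHER: 16
  PH_LHD: 21
  PH_RESP: 29
  CTEPH: 59
# Sub-study sizes per group: LGE imaging split is fixed (31 / 128); the phase
# contrast (106 total) and echo (195 total) splits are proportional.
subsets:
  lge: {NO_PH: 31, PH: 128}
  phase_contrast: {NO_PH: 18, PH: 88}
  echo: {NO_PH: 33, PH: 162}
n_non_diagnostic: 0
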