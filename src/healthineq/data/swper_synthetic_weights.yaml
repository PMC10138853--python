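# SYNTHETIC example SWPER-style scoring weights.
#
# These are NOT the published SWPER Global principal-component loadings,
# standardization constants or tertile cutpoints; those are not reproduced
# here and must be transcribed from the SWPER Global publication by the user.
# This file demonstrates the expected shape: three domains, each with a
# loading, center and scale for all 14 DHS-available items, optional coded
# item ranges, and two strictly increasing cutpoints (low < c1 <= medium <
# c2 <= high).  Values below are round numbers chosen so that each domain
# loads mainly on its own items.
domains:
  attitude_to_violence:
    loadings:
      beat_goes_out: 0.40
      beat_neglects_children: 0.40
      beat_argues: 0.40
      beat_refuses_sex: 0.40
      beat_burns_food: 0.40
      freq_reading: 0.02
      education_years: 0.01
      age_first_cohabitation: 0.0
      age_first_birth: 0.0
      age_difference: 0.0
      education_difference: 0.0
      decide_health: 0.0
      decide_purchases: 0.0
      decide_visits: 0.0
    centers:
      beat_goes_out: 0.5
      beat_neglects_children: 0.5
      beat_argues: 0.5
      beat_refuses_sex: 0.5
      beat_burns_food: 0.5
      freq_reading: 0.5
      education_years: 3.0
    scales:
      education_years: 4.0
    item_ranges:
      beat_goes_out: [0, 1]
      beat_neglects_children: [0, 1]
      beat_argues: [0, 1]
      beat_refuses_sex: [0, 1]
      beat_burns_food: [0, 1]
    cutpoints: [-0.4, 0.5]
  social_independence:
    loadings:
      beat_goes_out: 0.0
      beat_neglects_children: 0.0
      beat_argues: 0.0
      beat_refuses_sex: 0.0
      beat_burns_food: 0.0
      freq_reading: 0.35
      education_years: 0.45
      age_first_cohabitation: 0.30
      age_first_birth: 0.30
      age_difference: -0.10
      education_difference: 0.20
      decide_health: 0.0
      decide_purchases: 0.0
      decide_visits: 0.0
    centers:
      freq_reading: 0.5
      education_years: 3.0
      age_first_cohabitation: 18.0
      age_first_birth: 20.0
      age_difference: 5.0
      education_difference: -1.0
    scales:
      education_years: 4.0
      age_first_cohabitation: 4.0
      age_first_birth: 4.0
      age_difference: 5.0
      education_difference: 3.0
    cutpoints: [-0.3, 0.6]
  decision_making:
    loadings:
      beat_goes_out: 0.0
      beat_neglects_children: 0.0
      beat_argues: 0.0
      beat_refuses_sex: 0.0
      beat_burns_food: 0.0
      freq_reading: 0.0
      education_years: 0.02
      age_first_cohabitation: 0.0
      age_first_birth: 0.0
      age_difference: 0.0
      education_difference: 0.0
      decide_health: 0.55
      decide_purchases: 0.55
      decide_visits: 0.55
    centers:
      decide_health: 2.0
      decide_purchases: 2.0
      decide_visits: 2.0
      education_years: 3.0
    scales:
      education_years: 4.0
    item_ranges:
      decide_health: [1, 3]
      decide_purchases: [1, 3]
      decide_visits: [1, 3]
    cutpoints: [-0.5, 0.5]
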