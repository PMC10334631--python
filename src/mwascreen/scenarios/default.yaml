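n_patients: 2618
coverage_start: '2002-01-01'
coverage_end: '2015-12-31'
entry_start: '2004-01-01'
entry_end: '2015-12-31'
p_male: 0.6600458365164248
age_group_probs:
- 0.03666921313980138
- 0.10542398777692895
- 0.22841864018334607
- 0.2994652406417112
- 0.2635599694423224
- 0.06646294881588999
treatment_category_probs:
- 0.19404125286478227
- 0.11229946524064172
- 0.016042780748663103
- 0.2620320855614973
- 0.19786096256684493
- 0.21772345301757068
cci_probs:
- 0.07639419404125286
- 0.3116883116883117
- 0.6119174942704354
covariate_log_hrs:
  sex:female: -0.1
  age_group:40-49: 0.1
  age_group:50-59: 0.25
  age_group:60-69: 0.45
  age_group:70-79: 0.8
  age_group:>79: 1.3
  treatment_category:colonoscopy_only: 1.0
  treatment_category:operation_chemo: 0.35
  treatment_category:operation_radio: 0.3
  treatment_category:operation_both: 0.55
  treatment_category:chemo_or_radio_without_operation: 1.1
  cci_category:1-2: 0.15
  cci_category:3+: 0.4
baseline_hazard_cancer:
- 0.9
- 35000.0
baseline_hazard_other:
- 1.1
- 50000.0
drugs:
- atc_code: N07AA02
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: -0.8
  log_hr_cancer_specific: -0.8
  rx_rate: 4.0
- atc_code: N01AH01
  p_incident: 0.06
  p_prevalent: 0.03
  log_hr_all_cause: -0.7
  log_hr_cancer_specific: -0.7
  rx_rate: 4.0
- atc_code: A02AA04
  p_incident: 0.1
  p_prevalent: 0.05
  log_hr_all_cause: 0.7
  log_hr_cancer_specific: 0.7
  rx_rate: 4.0
- atc_code: G03DA04
  p_incident: 0.05
  p_prevalent: 0.03
  log_hr_all_cause: 0.8
  log_hr_cancer_specific: 0.8
  rx_rate: 4.0
- atc_code: B01AC06
  p_incident: 0.1
  p_prevalent: 0.06
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A10BA02
  p_incident: 0.08
  p_prevalent: 0.05
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: C10AA01
  p_incident: 0.08
  p_prevalent: 0.05
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AA01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AB01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AC01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AD01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AE01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AF01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AG01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AH01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AI01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AJ01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AK01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AL01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
- atc_code: A01AM01
  p_incident: 0.08
  p_prevalent: 0.04
  log_hr_all_cause: 0.0
  log_hr_cancer_specific: 0.0
  rx_rate: 4.0
prevalent_continue_prob: 0.5
anticancer_prefixes:
- L01
- L02
p_anticancer_rx: 0.3
seed: 20230710
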