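# Column-map profile: source variable name -> canonical morbmap field.
# DHS variable codes differ between releases; edit this profile rather than
# the reader.  The values below are the DHS-VI recode names used by the
# 2008 Egypt child recode file.
child_id: CASEID
diarrhoea: H11          # had diarrhoea recently (recoded to 0/1)
fever: H22              # had fever in last two weeks
cough: H31              # had cough in last two weeks
child_age_months: HW1
sex: B4
maternal_age_first_birth_years: V212
bmi: V445               # stored as BMI*100 in DHS; divide_bmi_by: 100 applies
residence: V025
household_size: V136
antenatal_visits: M14
place_of_delivery: M15
working_status: V714
wealth_quintile: V190
mother_education: V106
region_id: SGOVERN      # governorate code 1..27
divide_bmi_by: 100
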