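record_id,user_id,profession,encounter_type,appointment_date,entry_date,referral_date,referral_source,visit_reason,no_show
r01,u01,nurse,follow_up,2016-11-01,2016-11-01,,,counseling,false
r02,u01,nurse,follow_up,2016-11-01,2016-11-02,,,counseling,false
r03,u01,nurse,follow_up,2016-11-01,2016-11-01,,,other,false
r04,u02,dietitian,initial,2016-11-01,2016-11-01,2016-10-15,physician,assessment,false
r05,u02,dietitian,initial,2016-11-01,2016-11-01,2016-10-15,,assessment,false
r06,u02,dietitian,initial,2016-11-01,2016-11-01,1900-01-01,physician,assessment,false
r07,u03,social_worker,follow_up,2016-11-02,2016-11-01,,,counseling,false
r08,u03,social_worker,follow_up,2007-06-01,2007-06-01,,,counseling,false
r09,u03,social_worker,follow_up,2016-06-01,2016-09-30,,,education,false
r10,u03,social_worker,follow_up,2016-06-01,2016-10-01,,,education,false
r11,u04,pharmacist,initial,2016-11-01,2016-11-01,2016-05-01,physician,treatment,true
r12,u04,pharmacist,initial,2016-11-02,2016-11-02,2016-05-01,physician,treatment,false
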