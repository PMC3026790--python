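guideline,sex,nnt,events_avoided_per_1000,cost_per_event_avoided,expected_cost,p_event
us1,male,7.0,142.6,129428,,
us2,male,6.7,150.4,139204,,
us3,male,7.6,132.3,117269,15509,0.548
us4,male,6.6,151.4,141185,,
canada,male,6.6,152.8,147705,,
european,male,6.5,153.3,152385,,
british,male,6.5,153.8,156817,,
australia,male,6.5,153.9,157186,24186,0.527
statin_ace_no_guideline,male,14.4,81.0,63708,,
no_treatment,male,,,,,0.685
us1,female,6.9,145.6,134655,,
us2,female,6.6,151.8,144773,,
us3,female,7.5,133.0,115999,15433,0.412
us4,female,6.6,152.5,147011,,
canada,female,6.5,153.6,153952,,
european,female,6.5,153.9,158784,,
british,female,6.5,154.1,163488,,
australia,female,6.5,154.3,163775,25267,0.390
statin_ace_no_guideline,female,11.7,70.7,75886,,
no_treatment,female,,,,,0.545
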