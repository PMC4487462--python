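id,label,cluster,denominator,orientation,province_total
active_treatment_centers,Active treatment centers,institutional,1000,higher_is_better,56
active_beds,Active beds at treatment centers,institutional,1000,higher_is_better,43
active_health_centers,Active health centers,institutional,1000,higher_is_better,52
clinical_labs,Clinical laboratory centers,institutional,1000,higher_is_better,49
pharmacies,Pharmacy,institutional,1000,higher_is_better,64
radiography_centers,Radiography centers,institutional,1000,higher_is_better,34
rehabilitation_centers,Rehabilitation centers,institutional,1000,higher_is_better,61
urban_health_centers,Urban health centers,institutional,1000,higher_is_better,34
internists,Internist,human_resource,1000,higher_is_better,49
cardiologists,Cardiologist,human_resource,1000,higher_is_better,40
pediatricians,Pediatricians,human_resource,1000,higher_is_better,46
psychiatrists,Psychiatrists,human_resource,1000,higher_is_better,59
dermatologists,Dermatologist,human_resource,1000,higher_is_better,58
general_surgeons,General surgery specialist,human_resource,1000,higher_is_better,40
urologists,Urologists,human_resource,1000,higher_is_better,52
orthopedists,Orthopedist,human_resource,1000,higher_is_better,49
neurologists,Neurologist,human_resource,1000,higher_is_better,46
ent_specialists,ENT specialist,human_resource,1000,higher_is_better,46
ophthalmologists,Eye specialist (ophthalmologist),human_resource,1000,higher_is_better,43
gynecologists,Gynecologist,human_resource,1000,higher_is_better,52
anesthesiologists,Anesthesiologist,human_resource,1000,higher_is_better,55
radiotherapists,Radiotherapist,human_resource,1000,higher_is_better,34
pathologists,Pathologist,human_resource,10000,higher_is_better,62
dentists,Dentist,human_resource,1000,higher_is_better,43
pharmacologists,Pharmacologist,human_resource,1000,higher_is_better,52
paramedical_staff,Paramedical,human_resource,1000,higher_is_better,37
infectious_disease_specialists,Infectious diseases specialist,human_resource,1000,higher_is_better,58
general_practitioners,General practitioner,human_resource,1000,higher_is_better,49
rural_health_houses,Rural active health house,rural_institutional,1000,higher_is_better,61
rural_health_centers,Rural active health center,rural_institutional,1000,higher_is_better,31
villages_covered_by_health_house,Percentage of villages covered by rural active health house,rural_institutional,1000,higher_is_better,55
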