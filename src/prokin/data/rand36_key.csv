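subscale,item_id,n_levels,reverse
physical_functioning,3,3,False
physical_functioning,4,3,False
physical_functioning,5,3,False
physical_functioning,6,3,False
physical_functioning,7,3,False
physical_functioning,8,3,False
physical_functioning,9,3,False
physical_functioning,10,3,False
physical_functioning,11,3,False
physical_functioning,12,3,False
role_limitations_physical,13,2,True
role_limitations_physical,14,2,True
role_limitations_physical,15,2,True
role_limitations_physical,16,2,True
role_limitations_emotional,17,2,True
role_limitations_emotional,18,2,True
role_limitations_emotional,19,2,True
social_functioning,20,5,True
social_functioning,32,5,False
pain,21,6,True
pain,22,5,True
mental_health,24,6,True
mental_health,25,6,True
mental_health,26,6,False
mental_health,28,6,True
mental_health,30,6,False
vitality,23,6,False
vitality,27,6,False
vitality,29,6,True
vitality,31,6,True
general_health_perception,1,5,True
general_health_perception,33,5,True
general_health_perception,34,5,False
general_health_perception,35,5,True
general_health_perception,36,5,False
health_change,2,5,True
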