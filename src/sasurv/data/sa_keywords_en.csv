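pattern,modality
suicide attempts?,other
attempted suicide,other
suicidal act,other
tried to kill (?:him|her|them)self,other
intentional drug overdose,intentional-drug-overdose
voluntary drug intoxication,intentional-drug-overdose
intentional medication overdose,intentional-drug-overdose
attempted hanging,hanging
hanging attempt,hanging
jumped? from (?:a )?height,jump-from-height
voluntary defenestration,jump-from-height
self-inflicted wrist laceration,phlebotomy
deep self-inflicted wrist cutting,phlebotomy
self-inflicted gunshot wound,firearm
intentional drowning,drowning
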