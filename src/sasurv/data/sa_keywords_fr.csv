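pattern,modality
tentatives? de suicide,other
autolyse,other
intoxication médicamenteuse volontaire,intentional-drug-overdose
ingestion médicamenteuse volontaire,intentional-drug-overdose
tentative de pendaison,hanging
défenestration volontaire,jump-from-height
phlébotomie,phlebotomy
plaie par arme à feu auto-infligée,firearm
noyade volontaire,drowning
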