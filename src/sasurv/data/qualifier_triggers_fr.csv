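qualifier,trigger,direction,window
negation,pas de,pre,8
negation,aucun,pre,8
negation,aucune,pre,8
negation,sans,pre,8
negation,nie,pre,8
negation,absence de,pre,8
family,mère,both,8
family,père,both,8
family,frère,both,8
family,sœur,both,8
family,oncle,both,8
family,tante,both,8
family,antécédents familiaux de,pre,8
history,antécédent de,pre,8
history,antécédents de,pre,8
history,ancien,pre,8
history,ancienne,pre,8
history,ans auparavant,post,8
hypothesis,suspicion de,pre,8
hypothesis,risque de,pre,8
hypothesis,hypothèse de,pre,8
reported_speech,rapporte,pre,8
reported_speech,selon,pre,8
reported_speech,dit avoir,pre,8
reported_speech,déclare,pre,8
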