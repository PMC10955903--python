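qualifier,trigger,direction,window
negation,no,pre,8
negation,not,pre,8
negation,denies,pre,8
negation,denied,pre,8
negation,without,pre,8
negation,no evidence of,pre,8
family,mother,both,8
family,father,both,8
family,brother,both,8
family,sister,both,8
family,grandmother,both,8
family,grandfather,both,8
family,uncle,both,8
family,aunt,both,8
family,family history of,pre,8
history,history of,pre,8
history,previous,pre,8
history,prior,pre,8
history,past,pre,8
history,years ago,post,8
hypothesis,possible,pre,8
hypothesis,suspected,pre,8
hypothesis,suspicion of,pre,8
hypothesis,risk of,pre,8
reported_speech,reports,pre,8
reported_speech,reported,pre,8
reported_speech,according to,pre,8
reported_speech,states that,pre,8
reported_speech,said that,pre,8
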