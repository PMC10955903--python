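pattern,modality
(?:previous|prior|past) suicide attempts?,other
history of suicide attempts?,other
suicide attempt history,other
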