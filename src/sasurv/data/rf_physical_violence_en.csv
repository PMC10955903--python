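pattern,modality
physical violence,other
physical abuse,other
physical assault,other
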