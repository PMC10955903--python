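pattern,modality
antécédents? de tentatives? de suicide,other
tentative de suicide antérieure,other
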