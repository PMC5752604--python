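# target no-intervention deaths per pregnancy, by sub-condition
atonic_uterus: 0.002
eclampsia: 0.0015
sepsis: 0.003
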