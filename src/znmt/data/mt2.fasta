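>MT2_HUMAN canonical metallothionein-2A, initiator Met retained
MDPNCSCAAGDSCTCAGSCKCKECKCTSCKKSCCSCCPVGCAKCAQGCICKGASDKCSCCA
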