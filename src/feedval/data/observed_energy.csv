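# In vivo observed mean DE/ME (kcal/kg DM) of each food waste source with the
# margin of error of the 95% confidence interval of the observed population,
# used as the reference against which equation predictions are judged.
quantity,ingredient,observed_mean,margin
DE,FW,5057,259
DE,SMW,5071,131
DE,FVW,2570,251
ME,FW,4820,231
ME,SMW,4922,101
ME,FVW,2460,229
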