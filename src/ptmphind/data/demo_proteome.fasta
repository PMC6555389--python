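>sp|P10001|DEMO1_SYN synthetic demo kinase substrate
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK
>sp|P10002|DEMO2_SYN synthetic demo phosphoprotein
MSGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLT
>sp|P10003|DEMO3_SYN synthetic demo scaffold
MADEEKLPPGWEKRMSRSSGRVYYFNHITNASQWERPSGNSSSGGKNGQGEPARVRCSHL
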