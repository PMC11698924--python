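# SYNTHETIC species-presence table (offline stand-in for BRENDA lookups)
ec	status
1.1.1.27	present
1.1.1.30	present
1.2.4.1	present
1.3.5.1	present
2.3.1.16	present
2.3.3.1	present
2.6.1.42	present
2.7.1.30	present
5.4.2.11	present
7.1.1.2	present
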