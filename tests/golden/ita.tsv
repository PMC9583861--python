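# config_hash: 02ad46bda48c9c55
isomir	ita
syn-miR-1-5p—+2	1
syn-miR-1-5p—0	3
syn-miR-10-5p—0	3
syn-miR-12-5p—+2	2
syn-miR-12-5p—0	3
syn-miR-13-5p—0	4
syn-miR-14-5p—0	2
syn-miR-15-5p—+1	5
syn-miR-16-5p—+1	2
syn-miR-17-5p—+2	2
syn-miR-18-5p—-1	1
syn-miR-18-5p—0	1
syn-miR-19-5p—+1	1
syn-miR-19-5p—0	1
syn-miR-20-5p—+1	1
syn-miR-20-5p—0	2
syn-miR-4-5p—0	2
syn-miR-5-5p—-1	1
syn-miR-5-5p—0	1
syn-miR-6-5p—0	1
syn-miR-7-5p—+2	1
syn-miR-7-5p—0	1
syn-miR-8-5p—+1	1
syn-miR-8-5p—0	1
syn-miR-9-5p—+1	1
syn-miR-9-5p—0	2
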