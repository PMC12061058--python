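# description: distance from foveal center (um) for nine eyes, each measured independently by two graders
# units: um
id,g1,g2
1,977,968
2,1552,1642
3,555,640
4,1366,1409
5,1426,1496
6,2295,2297
7,1393,1430
8,718,634
9,1768,1820
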