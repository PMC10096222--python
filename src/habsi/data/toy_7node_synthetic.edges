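# Synthetic toy contact network: seven nodes, eight ties.
# The ties 1-3, 1-4, 2-4 and 4-6 are fixed by the documented worked trace;
# the remaining four are fixed filler edges so toy tests stay stable.
1 2
1 3
1 4
2 4
3 5
4 5
4 6
5 7
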