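attribute,CM033Q01,CM474Q01,CM155Q01,CM155Q04,CM411Q01,CM411Q02,CM803Q01,CM442Q02,CM034Q01
a1,0,0,1,1,0,0,0,0,0
a2,1,0,0,0,0,0,0,0,1
a3,0,1,0,0,1,0,0,1,0
a4,0,0,0,0,0,1,1,0,0
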