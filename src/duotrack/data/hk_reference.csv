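date,hi
2014-06-01,0.3243
2019-04-01,0.3542
2019-12-31,0.3677
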