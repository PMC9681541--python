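drug,m,n,count
psoralen,1,3,1
psoralen,2,2,3
psoralen,2,3,10
psoralen,3,3,2
azathioprine,1,2,1
azathioprine,1,3,1
azathioprine,2,2,5
azathioprine,2,3,9
azathioprine,3,3,4
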