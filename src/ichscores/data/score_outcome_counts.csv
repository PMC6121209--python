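system,score,dead,alive
ich,0,2,9
ich,1,6,20
ich,2,15,15
ich,3,19,2
ich,4,12,0
ich,5,6,0
ich,6,1,0
modified_new_ich,0,0,1
modified_new_ich,1,0,2
modified_new_ich,2,7,21
modified_new_ich,3,10,15
modified_new_ich,4,27,6
modified_new_ich,5,16,1
modified_new_ich,6,1,0
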