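# Common English onomatopoeia. One lowercase word per line.
# A response on this list imitates a sound rather than naming the picture
# and is coded as a non-response (NR).
achoo
baa
bang
beep
boom
buzz
chirp
clang
cluck
crackle
ding
fizz
growl
hiss
honk
meow
moo
neigh
nigh
oink
purr
quack
ribbit
screech
sizzle
splash
swish
thud
thump
tick
tock
vroom
whirr
whoosh
woof
zoom
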